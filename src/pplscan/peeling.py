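"""Two-locus pedigree likelihoods by Elston–Stewart peeling.

The hidden state of each individual is the ordered (phased) two-locus
genotype: (paternal trait allele, paternal marker allele, maternal trait
allele, maternal marker allele), 16 states for two diallelic loci.  The
trait allele is indexed 1 = disease allele; marker allele 1 = the map's
``allele2`` (the minor allele, frequency = MAF).

Likelihood factors:

* founder prior: Hardy–Weinberg at each locus, linkage equilibrium between
  them (or explicit haplotype frequencies, used by the LD/PPLD machinery);
* transmission: each parent passes one of its two haplotypes intact with
  probability (1−θ)/2 each, or a recombinant with probability θ/2;
* per-individual evidence: penetrance (or a normal density for quantitative
  traits) times the indicator of the observed unordered marker genotype.

Peeling is implemented as variable elimination over the pedigree's factor
graph with a greedy smallest-clique ordering; on loopless pedigrees every
intermediate factor stays small.  All per-individual evidence carries an
optional leading batch axis so thousands of trait models (or permuted
phenotype vectors) are evaluated in one pass.
"""

from __future__ import annotations

import string

import numpy as np

from .pedio import Pedigree, PedigreeError

N_STATES = 16

# state index = ((pat_trait*2 + pat_mark)*2 + mat_trait)*2 + mat_mark
_IDX = np.arange(N_STATES)
PAT_TRAIT = (_IDX >> 3) & 1
PAT_MARK = (_IDX >> 2) & 1
MAT_TRAIT = (_IDX >> 1) & 1
MAT_MARK = _IDX & 1
TRAIT_DOSE = PAT_TRAIT + MAT_TRAIT    # disease-allele count, 0..2
MARK_DOSE = PAT_MARK + MAT_MARK      # minor-allele count, 0..2


def gamete_probs(theta: float) -> np.ndarray:
    """(16, 4) matrix: P(gamete (t, m) | parent ordered state), given θ."""
    g = np.zeros((N_STATES, 4))
    for s in range(N_STATES):
        pt, pm, mt, mm = (s >> 3) & 1, (s >> 2) & 1, (s >> 1) & 1, s & 1
        for (t, m), p in (
            ((pt, pm), (1 - theta) / 2),
            ((mt, mm), (1 - theta) / 2),
            ((pt, mm), theta / 2),
            ((mt, pm), theta / 2),
        ):
            g[s, t * 2 + m] += p
    return g


def _transmission_tensor_uncached(theta: float) -> np.ndarray:
    g = gamete_probs(theta)
    child_pat = PAT_TRAIT * 2 + PAT_MARK  # child's paternal gamete index
    child_mat = MAT_TRAIT * 2 + MAT_MARK
    return g[:, child_pat].T[:, :, None] * g[:, child_mat].T[:, None, :]


_TRANS_CACHE: dict = {}


def transmission_tensor(theta: float) -> np.ndarray:
    """(16, 16, 16): P(child state | father state, mother state).

    Cached per θ; callers must not mutate the returned array."""
    key = round(float(theta), 12)
    t = _TRANS_CACHE.get(key)
    if t is None:
        t = _transmission_tensor_uncached(theta)
        t.setflags(write=False)
        _TRANS_CACHE[key] = t
    return t


def founder_prior(p_disease: float, maf: float,
                  haplotype_freqs: np.ndarray | None = None) -> np.ndarray:
    """(16,) prior over ordered founder states.

    Default: HWE at both loci, linkage equilibrium.  ``haplotype_freqs``
    (shape (2, 2), indexed [trait allele, marker allele], summing to 1)
    overrides the equilibrium assumption for association (PPLD) models.
    """
    if haplotype_freqs is None:
        if not 0.0 < p_disease < 1.0:
            raise ValueError(f"disease allele frequency outside (0,1): {p_disease}")
        pt = np.array([1 - p_disease, p_disease])
        pm = np.array([1 - maf, maf])
        h = pt[:, None] * pm[None, :]
    else:
        h = np.asarray(haplotype_freqs, dtype=float)
        if h.shape != (2, 2) or not np.isclose(h.sum(), 1.0):
            raise ValueError("haplotype_freqs must be 2x2 and sum to 1")
    return h[PAT_TRAIT, PAT_MARK] * h[MAT_TRAIT, MAT_MARK]


def marker_indicator(genotype) -> np.ndarray:
    """(16,) indicator of an unordered marker genotype (0 allele = missing)."""
    a, b = genotype
    if a == 0 or b == 0:
        return np.ones(N_STATES)
    dose = (a - 1) + (b - 1)
    return (MARK_DOSE == dose).astype(float)


def dichotomous_evidence(status, f) -> np.ndarray:
    """(…, 16) evidence for one individual under penetrances ``f`` (…, 3).

    ``status``: "affected", "unaffected" or "unknown".
    """
    f = np.asarray(f, dtype=float)
    if status == "affected":
        return f[..., TRAIT_DOSE]
    if status == "unaffected":
        return 1.0 - f[..., TRAIT_DOSE]
    return np.ones(f.shape[:-1] + (N_STATES,))


def quantitative_evidence(z, means) -> np.ndarray:
    """(…, 16) normal density evidence, unit residual SD; NaN z → flat."""
    means = np.asarray(means, dtype=float)
    if z is None or (isinstance(z, float) and np.isnan(z)):
        return np.ones(means.shape[:-1] + (N_STATES,))
    mu = means[..., TRAIT_DOSE]
    return np.exp(-0.5 * (z - mu) ** 2) / np.sqrt(2 * np.pi)


# ---------------------------------------------------------------------------
# Variable elimination

_LETTERS = string.ascii_lowercase


def _product_size(var_sets):
    vs = set()
    for v in var_sets:
        vs |= v
    return len(vs)


def eliminate(factors, variables):
    """Sum out ``variables`` from a list of (vars-tuple, array) factors.

    Arrays have shape (batch..., 16**len(vars)) unrolled as one axis per
    variable; a leading batch axis is optional and broadcast via ellipsis.
    Returns the scalar (or (batch,)) sum over everything.
    """
    factors = [(tuple(vs), np.asarray(arr)) for vs, arr in factors]
    remaining = set(variables)
    while remaining:
        # greedy: eliminate the variable giving the smallest joint factor
        best_v, best_size = None, None
        for v in remaining:
            size = _product_size([set(vs) for vs, _ in factors if v in vs])
            if best_size is None or size < best_size:
                best_v, best_size = v, size
        v = best_v
        involved = [(vs, arr) for vs, arr in factors if v in vs]
        rest = [(vs, arr) for vs, arr in factors if v not in vs]
        out_vars = tuple(
            sorted({u for vs, _ in involved for u in vs} - {v})
        )
        # build einsum over the involved factors
        letter = {u: _LETTERS[i] for i, u in enumerate(out_vars + (v,))}
        spec = ",".join("..." + "".join(letter[u] for u in vs)
                        for vs, _ in involved)
        spec += "->..." + "".join(letter[u] for u in out_vars)
        new_arr = np.einsum(spec, *[arr for _, arr in involved],
                            optimize=True)
        rest.append((out_vars, new_arr))
        factors = rest
        remaining.discard(v)
    # all variables gone: multiply the residual (batch-only) factors
    result = np.array(1.0)
    for _, arr in factors:
        result = result * arr
    return result


def family_likelihood(pedigree: Pedigree, marker_genotypes: dict,
                      evidence: dict, theta: float,
                      p_disease, maf: float,
                      haplotype_freqs: np.ndarray | None = None,
                      trans: np.ndarray | None = None):
    """Two-locus pedigree likelihood.

    Parameters
    ----------
    marker_genotypes : dict individual_id -> (a, b) allele pair (0 missing)
    evidence : dict individual_id -> (batch..., 16) trait evidence array
        (penetrance or density already applied; flat array for unknowns)
    theta : recombination fraction between trait locus and marker
    p_disease : disease allele frequency, scalar or (batch,) array
    maf : marker minor-allele frequency
    haplotype_freqs : optional (2,2) trait×marker haplotype frequencies
        (overrides p_disease/maf; used for association models at θ=0)
    trans : optional precomputed transmission tensor for ``theta``

    Returns the likelihood, scalar or (batch,)-shaped.
    """
    if pedigree.loops_flag:
        raise PedigreeError(
            f"family {pedigree.family_id}: looped pedigree unsupported "
            "by the likelihood engine"
        )
    if trans is None:
        trans = transmission_tensor(theta)

    p_disease_arr = np.asarray(p_disease, dtype=float)
    batched_p = p_disease_arr.ndim > 0

    factors = []
    for m in pedigree:
        iid = m.individual_id
        ev = np.asarray(evidence.get(iid, np.ones(N_STATES)), dtype=float)
        ind = marker_indicator(marker_genotypes.get(iid, (0, 0)))
        unary = ev * ind
        if m.is_founder:
            if haplotype_freqs is not None:
                prior = founder_prior(0.5, maf, haplotype_freqs)
                unary = unary * prior
            elif batched_p:
                priors = np.stack(
                    [founder_prior(pd_, maf) for pd_ in p_disease_arr]
                )
                unary = unary * priors
            else:
                unary = unary * founder_prior(float(p_disease_arr), maf)
        factors.append(((iid,), unary))
    for m in pedigree.nonfounders:
        factors.append(
            ((m.individual_id, m.father_id, m.mother_id), trans)
        )
    return eliminate(factors, [m.individual_id for m in pedigree])


def enumeration_likelihood(pedigree: Pedigree, marker_genotypes: dict,
                           evidence: dict, theta: float,
                           p_disease: float, maf: float) -> float:
    """Exhaustive-enumeration likelihood: the independent oracle.

    Builds the full joint tensor over all 16^n ordered two-locus genotype
    configurations by plain broadcasting and sums it.  Exponential in family
    size — intended for pedigrees of ≤6 members in tests.
    """
    members = list(pedigree)
    n = len(members)
    order = {m.individual_id: i for i, m in enumerate(members)}
    trans = transmission_tensor(theta)
    joint = np.ones((N_STATES,) * n)
    for m in members:
        iid = m.individual_id
        unary = (
            np.asarray(evidence.get(iid, np.ones(N_STATES)), dtype=float)
            * marker_indicator(marker_genotypes.get(iid, (0, 0)))
        )
        if m.is_founder:
            unary = unary * founder_prior(p_disease, maf)
        shape = [1] * n
        shape[order[iid]] = N_STATES
        joint = joint * unary.reshape(shape)
    for m in pedigree.nonfounders:
        # place the (child, father, mother) axes of the transmission tensor
        # into the joint's axis order via transpose + reshape
        axes = [order[m.individual_id], order[m.father_id], order[m.mother_id]]
        perm = sorted(range(3), key=lambda k: axes[k])
        arr_t = np.transpose(trans, perm)
        view_shape = [1] * n
        for k in perm:
            view_shape[axes[k]] = N_STATES
        joint = joint * arr_t.reshape(view_shape)
    return float(joint.sum())
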