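"""Trait models and the discrete integration grids behind the PPL.

The Bayes ratio integrates the admixture likelihood ratio over a discrete
grid of trait models (penetrance vectors or genotypic means plus disease
allele frequency), admixture proportions α, and recombination fractions θ,
all with uniform prior weights.  Penetrance/mean triples are restricted to
ordered (monotone) vectors so the disease allele acts in one direction.

Three resolutions are provided: ``default`` (the analysis grid),
``coarse`` (desk-scale simulation studies) and ``calibration`` (the
gene-dropping null, where many replicates are scanned).  Resolution is a
numerical choice; the prior probability of linkage stays 2% throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

#: prior probability of linkage
PRIOR_LINKAGE = 0.02

WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class TraitModel:
    """One trait-locus model.

    ``effects`` are penetrances (f0, f1, f2) for a dichotomous trait or
    genotypic means (μ0, μ1, μ2) on a z-score scale (unit residual SD) for
    a quantitative one, ordered by disease-allele count.  ``alpha`` is the
    admixture proportion of linked families.
    """

    kind: str                 # "dichotomous" | "quantitative"
    p_disease: float
    effects: tuple
    alpha: float = 1.0

    def __post_init__(self):
        if self.kind not in ("dichotomous", "quantitative"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if not 0.0 < self.p_disease < 1.0:
            raise ValueError("disease allele frequency outside (0,1)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha outside (0,1]")
        e = self.effects
        if len(e) != 3:
            raise ValueError("need three genotypic effects")
        monotone = (e[0] <= e[1] <= e[2]) or (e[0] >= e[1] >= e[2])
        if not monotone:
            raise ValueError(f"effects not ordered: {e}")
        if self.kind == "dichotomous" and not all(0 <= x <= 1 for x in e):
            raise ValueError("penetrance outside [0,1]")


def _ordered_triples(values) -> list[tuple]:
    """Monotone non-decreasing and non-increasing triples, deduplicated."""
    up = set(combinations_with_replacement(sorted(values), 3))
    down = {tuple(reversed(t)) for t in up}
    return sorted(up | down)


@dataclass
class TraitModelGrid:
    """Discrete (model, α, θ) grid with uniform prior weights."""

    kind: str
    effects: np.ndarray       # (M, 3)
    p_disease: np.ndarray     # (M,)
    model_weights: np.ndarray  # (M,)
    alphas: np.ndarray
    alpha_weights: np.ndarray
    thetas: np.ndarray
    theta_weights: np.ndarray
    prior_linkage: float = PRIOR_LINKAGE

    def __post_init__(self):
        for w in (self.model_weights, self.alpha_weights, self.theta_weights):
            if abs(float(np.sum(w)) - 1.0) > WEIGHT_TOL:
                raise ValueError("grid weights must sum to 1")
        if not 0.0 < self.prior_linkage < 1.0:
            raise ValueError("prior probability of linkage outside (0,1)")

    @property
    def n_models(self) -> int:
        return len(self.p_disease)

    def theta_index(self, theta: float) -> int:
        j = int(np.argmin(np.abs(self.thetas - theta)))
        if abs(self.thetas[j] - theta) > 1e-9:
            raise ValueError(f"theta {theta} not on grid")
        return j


def _build(kind, effect_values, p_values, alphas, thetas) -> TraitModelGrid:
    triples = _ordered_triples(effect_values)
    effects, pds = [], []
    for p in p_values:
        for t in triples:
            effects.append(t)
            pds.append(p)
    m = len(effects)
    alphas = np.asarray(alphas, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    return TraitModelGrid(
        kind=kind,
        effects=np.asarray(effects, dtype=float),
        p_disease=np.asarray(pds, dtype=float),
        model_weights=np.full(m, 1.0 / m),
        alphas=alphas,
        alpha_weights=np.full(len(alphas), 1.0 / len(alphas)),
        thetas=thetas,
        theta_weights=np.full(len(thetas), 1.0 / len(thetas)),
    )


THETAS_DEFAULT = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05,
                  0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5)
THETAS_COARSE = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
ALPHAS_DEFAULT = (0.2, 0.4, 0.6, 0.8, 1.0)
P_DISEASE_DEFAULT = (0.001, 0.01, 0.1, 0.5, 0.8)


def default_grid(kind: str = "dichotomous") -> TraitModelGrid:
    """The analysis-resolution grid."""
    if kind == "dichotomous":
        return _build(kind, np.round(np.arange(0, 1.01, 0.1), 1),
                      P_DISEASE_DEFAULT, ALPHAS_DEFAULT, THETAS_DEFAULT)
    return _build(kind, np.arange(-3.0, 3.01, 1.0),
                  P_DISEASE_DEFAULT, ALPHAS_DEFAULT, THETAS_DEFAULT)


def coarse_grid(kind: str = "dichotomous") -> TraitModelGrid:
    """Reduced grid for desk-scale simulation studies."""
    if kind == "dichotomous":
        return _build(kind, (0.0, 0.1, 0.5, 0.7, 0.9),
                      (0.001, 0.01, 0.1, 0.5), ALPHAS_DEFAULT, THETAS_COARSE)
    return _build(kind, (-3.0, -1.0, 0.0, 1.0, 3.0),
                  (0.001, 0.01, 0.1, 0.5), ALPHAS_DEFAULT, THETAS_COARSE)


def calibration_grid(kind: str = "dichotomous") -> TraitModelGrid:
    """Minimal grid for the many-replicate gene-dropping null."""
    if kind == "dichotomous":
        return _build(kind, (0.0, 0.5, 0.9),
                      (0.01, 0.1, 0.5), (0.5, 1.0), THETAS_COARSE)
    return _build(kind, (-2.0, 0.0, 2.0),
                  (0.01, 0.1, 0.5), (0.5, 1.0), THETAS_COARSE)


#: disease-model triples for the power-study grid: zero/low phenocopy,
#: moderate-to-high penetrance, dominant-leaning with recessive entries —
#: the informative corner of the default penetrance lattice
POWER_EFFECTS = (
    (0.0, 0.3, 0.5), (0.0, 0.5, 0.7), (0.0, 0.7, 0.9), (0.0, 0.9, 0.9),
    (0.0, 0.5, 0.9), (0.0, 0.0, 0.7), (0.0, 0.0, 0.9),
    (0.1, 0.5, 0.7), (0.1, 0.7, 0.9), (0.1, 0.9, 0.9), (0.1, 0.1, 0.9),
)


def power_grid(kind: str = "dichotomous") -> TraitModelGrid:
    """Reduced informative-model grid for desk-scale power studies.

    Restricting the mixture to plausible disease models (rather than the
    full lattice, most of which is uninformative at small sample sizes)
    keeps the Bayes ratio responsive in simulation studies; grid values
    are a subset of the default lattice.
    """
    if kind != "dichotomous":
        return coarse_grid(kind)
    effects, pds = [], []
    for p in (0.001, 0.01, 0.1):
        for e in POWER_EFFECTS:
            effects.append(e)
            pds.append(p)
    m = len(effects)
    return TraitModelGrid(
        kind=kind,
        effects=np.asarray(effects, dtype=float),
        p_disease=np.asarray(pds, dtype=float),
        model_weights=np.full(m, 1.0 / m),
        alphas=np.asarray(ALPHAS_DEFAULT, dtype=float),
        alpha_weights=np.full(len(ALPHAS_DEFAULT), 1.0 / len(ALPHAS_DEFAULT)),
        thetas=np.asarray(THETAS_COARSE, dtype=float),
        theta_weights=np.full(len(THETAS_COARSE), 1.0 / len(THETAS_COARSE)),
    )


GRID_PRESETS = {
    "default": default_grid,
    "coarse": coarse_grid,
    "calibration": calibration_grid,
    "power": power_grid,
}
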