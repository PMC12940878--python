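"""Pedigree, marker-map and phenotype I/O plus genetic map functions.

The on-disk dialect is pre-LINKAGE: whitespace-delimited rows of
``fam id father mother sex pheno a1 b1 a2 b2 ...`` with ``0`` for an absent
parent, a missing allele, or unknown sex.  One phenotype column is reserved
(and ignored); all analysis phenotypes live in a separate TSV keyed by
(family_id, individual_id).  Marker maps are PLINK-style
(``chrom name cM bp``) with a side TSV carrying allele labels and MAF.
Base-pair coordinates are 1-based; intervals are half-open [start, end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

MISSING_TOKENS = {".", "NA", "na", ""}

SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, dangling parents...)."""


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class Individual:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """One family: ordered members plus derived structure.

    ``loops_flag`` is true iff the marriage graph (couples contracted to
    nodes, edges to offspring couples) contains a cycle — e.g. first-cousin
    marriages.  Looped families are valid data but are rejected by the
    likelihood engine.
    """

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {m.individual_id: m for m in self.members}
        if len(self._by_id) != len(self.members):
            raise PedigreeError(
                f"family {self.family_id}: duplicate individual ids"
            )
        self._validate()

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def get(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    def children_of(self, individual_id: str) -> list[Individual]:
        return [
            m
            for m in self.members
            if individual_id in (m.father_id, m.mother_id)
        ]

    @property
    def loops_flag(self) -> bool:
        # Marriage graph: one node per individual, one per mating; an
        # undirected cycle through matings marks a pedigree loop.
        g = nx.Graph()
        for m in self.members:
            g.add_node(("i", m.individual_id))
        for m in self.nonfounders:
            mate = ("u", m.father_id, m.mother_id)
            g.add_edge(mate, ("i", m.father_id))
            g.add_edge(mate, ("i", m.mother_id))
            g.add_edge(mate, ("i", m.individual_id))
        try:
            nx.find_cycle(g)
            return True
        except nx.NetworkXNoCycle:
            return False

    def _validate(self) -> None:
        fid = self.family_id
        for m in self.members:
            if (m.father_id is None) != (m.mother_id is None):
                raise PedigreeError(
                    f"family {fid}, individual {m.individual_id}: "
                    "exactly one parent given (need both or neither)"
                )
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(
                        f"family {fid}: parent {pid} of {m.individual_id} "
                        "not in family"
                    )
        if not self.founders:
            raise PedigreeError(f"family {fid}: no founders")
        # acyclic parentage
        dg = nx.DiGraph()
        dg.add_nodes_from(m.individual_id for m in self.members)
        for m in self.nonfounders:
            dg.add_edge(m.father_id, m.individual_id)
            dg.add_edge(m.mother_id, m.individual_id)
        if not nx.is_directed_acyclic_graph(dg):
            raise PedigreeError(f"family {fid}: cyclic parentage")

    def ancestors(self, individual_id: str) -> set[str]:
        """All ancestors by exhaustive parent-chasing."""
        out: set[str] = set()
        stack = [individual_id]
        while stack:
            m = self._by_id[stack.pop()]
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in out:
                    out.add(pid)
                    stack.append(pid)
        return out


@dataclass
class MarkerMap:
    """Ordered marker table: chrom, name, position_cM (sex-averaged Kosambi),
    position_bp (1-based), allele labels, MAF (frequency of allele 2)."""

    table: pd.DataFrame  # columns: chrom, name, cM, bp, allele1, allele2, maf

    REQUIRED = ("chrom", "name", "cM", "bp", "allele1", "allele2", "maf")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"marker map missing columns: {missing}")
        t = self.table
        if ((t["maf"] < 0) | (t["maf"] > 0.5)).any():
            raise FormatError("MAF outside [0, 0.5]")
        for chrom, sub in t.groupby("chrom", sort=False):
            if not (np.diff(sub["bp"].to_numpy()) > 0).all():
                raise FormatError(f"chrom {chrom}: bp not strictly increasing")
            if not (np.diff(sub["cM"].to_numpy()) > 0).all():
                raise FormatError(f"chrom {chrom}: cM not strictly increasing")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return list(self.table["name"])

    def index_of(self, name: str) -> int:
        idx = self.table.index[self.table["name"] == name]
        if len(idx) == 0:
            raise KeyError(name)
        return int(self.table.index.get_loc(idx[0]))


@dataclass
class GenotypeMatrix:
    """individuals × markers grid of unordered allele pairs.

    ``alleles`` has shape (n_individuals, n_markers, 2) with entries 0
    (missing), 1, or 2 indexing each marker's two allele labels.
    """

    sample_ids: list[tuple[str, str]]  # (family_id, individual_id)
    marker_names: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.sample_ids), len(self.marker_names), 2):
            raise FormatError("genotype matrix shape mismatch")
        if not np.isin(self.alleles, (0, 1, 2)).all():
            raise FormatError("allele code outside {0,1,2}")
        self._row = {sid: i for i, sid in enumerate(self.sample_ids)}
        self._col = {n: j for j, n in enumerate(self.marker_names)}

    def genotype(self, family_id: str, individual_id: str, marker: str):
        return tuple(self.alleles[self._row[(family_id, individual_id)], self._col[marker]])

    def column(self, marker: str) -> np.ndarray:
        return self.alleles[:, self._col[marker], :]

    def rows_for_family(self, pedigree: Pedigree) -> dict[str, int]:
        return {
            m.individual_id: self._row[(pedigree.family_id, m.individual_id)]
            for m in pedigree
        }


PHENO_COLUMNS = [
    "family_id", "individual_id", "asd", "li", "ri", "piq", "celf_core",
    "reading_subtest_z", "oral_subtest_z", "intervention_history",
    "srs_t", "srs_rirb_t", "wave", "tier",
]


def empty_phenotype_table(sample_ids) -> pd.DataFrame:
    """Skeleton phenotype table for a roster, everything missing."""
    df = pd.DataFrame(
        {"family_id": [s[0] for s in sample_ids],
         "individual_id": [s[1] for s in sample_ids]}
    )
    for col in PHENO_COLUMNS[2:]:
        df[col] = None
    return df


# ---------------------------------------------------------------------------
# Genetic map functions (sex-averaged Kosambi units throughout)

def kosambi_theta(distance_cM: float) -> float:
    """Kosambi map function: θ = ½·tanh(2d) with d in Morgans."""
    if distance_cM < 0:
        raise ValueError(f"negative map distance: {distance_cM}")
    return 0.5 * math.tanh(2.0 * distance_cM / 100.0)


def kosambi_cM(theta: float) -> float:
    """Inverse Kosambi map function, θ ∈ [0, 0.5) → distance in cM."""
    if not 0.0 <= theta < 0.5:
        raise ValueError(f"recombination fraction outside [0, 0.5): {theta}")
    return 50.0 * math.atanh(2.0 * theta)


def haldane_theta(distance_cM: float) -> float:
    """Haldane map function θ = ½(1 − e^{−2d}); no interference."""
    if distance_cM < 0:
        raise ValueError(f"negative map distance: {distance_cM}")
    return 0.5 * (1.0 - math.exp(-2.0 * distance_cM / 100.0))


# ---------------------------------------------------------------------------
# Readers / writers

def _parse_parent(token: str) -> str | None:
    return None if token == "0" else token


def read_pedigree_file(path, marker_names=None):
    """Read a pre-LINKAGE pedigree file.

    Returns (pedigrees, genotypes, phenotype-table skeleton).  Genotype
    columns come in pairs after the six fixed columns; ``marker_names``
    labels them (defaults to M1..Mk).
    """
    rows = []
    geno_rows = []
    n_markers = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6 or (len(parts) - 6) % 2 != 0:
                raise FormatError(f"{path}:{lineno}: expected 6 + 2k columns")
            k = (len(parts) - 6) // 2
            if n_markers is None:
                n_markers = k
            elif k != n_markers:
                raise FormatError(f"{path}:{lineno}: inconsistent marker count")
            fam, iid, fa, mo, sex, _pheno = parts[:6]
            if sex not in SEX_CODES:
                raise FormatError(f"{path}:{lineno}: bad sex code {sex!r}")
            rows.append((fam, iid, _parse_parent(fa), _parse_parent(mo),
                         SEX_CODES[sex]))
            g = []
            for tok in parts[6:]:
                if tok not in ("0", "1", "2"):
                    raise FormatError(
                        f"{path}:{lineno}: allele {tok!r} outside map labels"
                    )
                g.append(int(tok))
            geno_rows.append(g)
    if not rows:
        raise FormatError(f"{path}: empty pedigree file")

    pedigrees = []
    current_fam = None
    members: list[Individual] = []
    for fam, iid, fa, mo, sex in rows:
        if fam != current_fam:
            if members:
                pedigrees.append(Pedigree(current_fam, members))
            current_fam, members = fam, []
        members.append(Individual(fam, iid, fa, mo, sex))
    pedigrees.append(Pedigree(current_fam, members))

    sample_ids = [(r[0], r[1]) for r in rows]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate (family, individual) keys")
    if marker_names is None:
        marker_names = [f"M{i + 1}" for i in range(n_markers)]
    alleles = np.array(geno_rows, dtype=np.int8).reshape(
        len(sample_ids), n_markers, 2
    )
    genotypes = GenotypeMatrix(sample_ids, list(marker_names), alleles)
    return pedigrees, genotypes, empty_phenotype_table(sample_ids)


def write_ped_map(pedigrees, genotypes: GenotypeMatrix, marker_map: MarkerMap,
                  phenotable: pd.DataFrame | None, out_prefix) -> dict:
    """Write <prefix>.ped / <prefix>.map / <prefix>.pheno.tsv.

    Round-trips bit-identically through :func:`read_pedigree_file` for
    structure and genotypes.
    """
    out_prefix = str(out_prefix)
    if not pedigrees:
        raise ValueError("refusing to write an empty cohort")
    seen = set()
    for ped in pedigrees:
        for m in ped:
            key = (m.family_id, m.individual_id)
            if key in seen:
                raise ValueError(f"duplicate key {key}")
            seen.add(key)

    ped_path = out_prefix + ".ped"
    with open(ped_path, "w") as fh:
        for ped in pedigrees:
            for m in ped:
                row = [
                    m.family_id, m.individual_id,
                    m.father_id or "0", m.mother_id or "0",
                    SEX_TO_CODE[m.sex], "0",
                ]
                g = genotypes.alleles[
                    genotypes._row[(m.family_id, m.individual_id)]
                ]
                row += [str(a) for a in g.reshape(-1)]
                fh.write(" ".join(row) + "\n")

    map_path = out_prefix + ".map"
    marker_map.table.to_csv(
        map_path, sep="\t", index=False,
        columns=["chrom", "name", "cM", "bp", "allele1", "allele2", "maf"],
    )
    paths = {"ped": ped_path, "map": map_path}
    if phenotable is not None:
        pheno_path = out_prefix + ".pheno.tsv"
        write_phenotype_table(phenotable, pheno_path)
        paths["pheno"] = pheno_path
    return paths


def read_marker_map(path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t"))


def _join_list(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "."
    if isinstance(v, (list, tuple, np.ndarray)):
        return ",".join(f"{x:g}" for x in v) if len(v) else "."
    return v


def _split_list(tok):
    if tok in MISSING_TOKENS or (isinstance(tok, float) and math.isnan(tok)):
        return None
    if isinstance(tok, str):
        return [float(x) for x in tok.split(",")]
    return [float(tok)]


def write_phenotype_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("reading_subtest_z", "oral_subtest_z"):
        if col in out:
            out[col] = out[col].map(_join_list)
    out.to_csv(path, sep="\t", index=False, na_rep=".")


def read_phenotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str,
                                            "individual_id": str},
                     na_values=sorted(MISSING_TOKENS - {""}),
                     keep_default_na=True)
    for col in ("reading_subtest_z", "oral_subtest_z"):
        if col in df:
            df[col] = df[col].map(_split_list)
    return df
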