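"""Motif occurrences to sensing matrix.

A 19-bp motif shared by several genes is a candidate *group identifier*
siRNA: one probe that knocks down a whole gene group. This module ingests a
motif-occurrence table (the shape a motif-discovery report exports), derives
each motif's maximum consensus sequence (MCS), prunes the siRNA-gene
bipartite network so that gene identities stay decodable, and assembles the
m x n sensing matrix Phi whose entry (i, j) is the percent identity between
motif i's MCS and its occurrence site on gene j, with columns scaled to unit
Euclidean norm. Coherence and restricted-isometry diagnostics quantify how
close the columns are to an orthonormal system.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .sequence_codec import normalize_sequence

logger = logging.getLogger("csrnai")

MOTIF_WIDTH = 19

OCCURRENCE_COLUMNS = ("motif_id", "gene_id", "start", "site", "p_value")


@dataclass(frozen=True)
class MotifOccurrence:
    """One match of a motif on a gene's forward strand (0-based start)."""

    motif_id: str
    gene_id: str
    start: int
    site: str
    p_value: float

    def __post_init__(self) -> None:
        if len(self.site) != MOTIF_WIDTH:
            raise ValueError(
                f"site length {len(self.site)} != {MOTIF_WIDTH} "
                f"(motif {self.motif_id}, gene {self.gene_id})"
            )
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")
        if self.start < 0:
            raise ValueError("start must be >= 0")


@dataclass
class MotifProfile:
    """A motif with its occurrence list and maximum consensus sequence."""

    motif_id: str
    occurrences: list[MotifOccurrence]
    e_value: float = 0.0
    mcs: str = ""

    def __post_init__(self) -> None:
        if not self.occurrences:
            raise ValueError(f"motif {self.motif_id} has no occurrences")
        if not self.mcs:
            self.mcs = compute_mcs(self)

    @property
    def gene_ids(self) -> list[str]:
        return [o.gene_id for o in self.occurrences]


def compute_mcs(profile: MotifProfile) -> str:
    """Per-position modal nucleotide across the occurrence sites.

    Ties break to the lexicographically smallest nucleotide (A<C<G<T).
    """
    sites = [normalize_sequence(o.site) for o in profile.occurrences]
    mcs = []
    for pos in range(MOTIF_WIDTH):
        counts: dict[str, int] = {}
        for s in sites:
            counts[s[pos]] = counts.get(s[pos], 0) + 1
        best = max(sorted(counts), key=lambda nt: counts[nt])
        mcs.append(best)
    return "".join(mcs)


def percent_identity(mcs: str, site: str) -> float:
    """Fraction of positions at which the site matches the consensus."""
    if len(mcs) != len(site):
        raise ValueError(f"length mismatch: {len(mcs)} vs {len(site)}")
    mcs = normalize_sequence(mcs)
    site = normalize_sequence(site)
    return sum(a == b for a, b in zip(mcs, site)) / len(mcs)


def complement_19mer(seq: str) -> str:
    """Reverse complement, for motifs discovered in mRNA space."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    return "".join(comp[ch] for ch in reversed(normalize_sequence(seq)))


def read_occurrences(table, complement: bool = False) -> list[MotifProfile]:
    """Group an occurrence table into motif profiles.

    ``table`` is a path to a TSV with header motif_id/gene_id/start/site/
    p_value, or an equivalent DataFrame. Occurrences are sorted by p-value
    within each motif; duplicate (motif, gene, start) rows are dropped with
    a warning. ``complement=True`` reverse-complements each site for inputs
    reported in mRNA coordinates.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t", dtype={"motif_id": str, "gene_id": str})
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    if df.empty:
        return []
    before = len(df)
    df = df.drop_duplicates(subset=["motif_id", "gene_id", "start"])
    if len(df) < before:
        logger.warning("dropped %d duplicate occurrence rows", before - len(df))
    profiles = []
    for motif_id, grp in df.groupby("motif_id", sort=True):
        occs = []
        for line_no, row in enumerate(grp.sort_values("p_value").itertuples(), 1):
            site = str(row.site)
            if complement:
                site = complement_19mer(site)
            try:
                occs.append(
                    MotifOccurrence(str(motif_id), str(row.gene_id),
                                    int(row.start), site, float(row.p_value))
                )
            except ValueError as exc:
                raise ValueError(f"motif {motif_id}, record {line_no}: {exc}") from exc
        profiles.append(MotifProfile(motif_id=str(motif_id), occurrences=occs))
    return profiles


# ---------------------------------------------------------------------------
# Network pruning
# ---------------------------------------------------------------------------

def is_low_complexity(mcs: str, max_modal_fraction: float = 0.8) -> bool:
    """True when one nucleotide occupies at least this fraction of positions.

    Near-homopolymer consensus sequences (AA...AC and the like) match
    everywhere and carry no group-identification information.
    """
    seq = normalize_sequence(mcs)
    top = max(seq.count(nt) for nt in "ACGT")
    return top / len(seq) >= max_modal_fraction


@dataclass
class PruneAudit:
    """Plain-text log of pruning actions, one removal per line."""

    lines: list[str] = field(default_factory=list)

    def record(self, action: str) -> None:
        self.lines.append(action)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.lines) + ("\n" if self.lines else ""))


def prune_network(profiles: list[MotifProfile], seed: int = 0,
                  max_modal_fraction: float = 0.8):
    """Prune the siRNA-gene network until gene identities are decodable.

    Iterates to a fixed point:

    a. motifs with low-complexity consensus sequences are discarded;
    b. genes sharing an identical motif-membership signature are collapsed
       to one seeded-random survivor (identically-covered genes cannot be
       told apart by any readout);
    c. strict 1-to-1 motif-gene pairs (the motif hits only that gene and
       the gene is hit only by that motif) are removed outright — such a
       probe is conventional, not compressive.

    Returns (pruned profiles, audit log). Pruning an already-pruned network
    is a no-op, so the operation is idempotent.
    """
    if not profiles:
        raise ValueError("no profiles to prune")
    rng = np.random.default_rng(seed)
    audit = PruneAudit()
    current = [
        MotifProfile(p.motif_id, list(p.occurrences), p.e_value, p.mcs)
        for p in profiles
    ]
    changed = True
    while changed:
        changed = False
        # (a) low-complexity MCS filter
        keep = []
        for p in current:
            if is_low_complexity(p.mcs, max_modal_fraction):
                audit.record(f"drop-motif\t{p.motif_id}\tlow-complexity MCS {p.mcs}")
                changed = True
            else:
                keep.append(p)
        current = keep
        if not current:
            raise ValueError("pruning removed every motif")
        # (b) collapse genes with identical motif-membership signatures
        signatures: dict[str, frozenset] = {}
        for p in current:
            for g in set(p.gene_ids):
                signatures.setdefault(g, set()).add(p.motif_id)  # type: ignore[arg-type]
        by_signature: dict[frozenset, list[str]] = {}
        for g, sig in signatures.items():
            by_signature.setdefault(frozenset(sig), []).append(g)
        doomed = set()
        for sig, genes in sorted(by_signature.items(), key=lambda kv: sorted(kv[1])[0]):
            if len(genes) > 1:
                genes = sorted(genes)
                survivor = genes[int(rng.integers(len(genes)))]
                for g in genes:
                    if g != survivor:
                        doomed.add(g)
                        audit.record(
                            f"drop-gene\t{g}\tduplicate motif signature of {survivor}"
                        )
                changed = True
        if doomed:
            current = _drop_genes(current, doomed, audit)
        # (c) strict 1-to-1 correspondences
        gene_cover: dict[str, set] = {}
        for p in current:
            for g in set(p.gene_ids):
                gene_cover.setdefault(g, set()).add(p.motif_id)
        keep = []
        for p in current:
            targets = set(p.gene_ids)
            if len(targets) == 1:
                g = next(iter(targets))
                if gene_cover[g] == {p.motif_id}:
                    audit.record(f"drop-pair\t{p.motif_id}\t{g}\t1-to-1 correspondence")
                    changed = True
                    continue
            keep.append(p)
        current = keep
        if not current:
            raise ValueError("pruning removed every motif")
    return current, audit


def _drop_genes(profiles, doomed, audit) -> list[MotifProfile]:
    out = []
    for p in profiles:
        occs = [o for o in p.occurrences if o.gene_id not in doomed]
        if not occs:
            audit.record(f"drop-motif\t{p.motif_id}\tall targets pruned")
            continue
        out.append(MotifProfile(p.motif_id, occs, p.e_value, p.mcs))
    return out


# ---------------------------------------------------------------------------
# Sensing matrix and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class SensingMatrix:
    """The m x n matrix Phi: rows are siRNAs/motifs, columns are genes."""

    entries: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    normalized: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def normalize_columns(self) -> "SensingMatrix":
        norms = np.linalg.norm(self.entries, axis=0)
        zero = np.where(norms == 0)[0]
        if zero.size:
            raise ValueError(
                f"all-zero column(s) for gene(s): {[self.col_ids[j] for j in zero]}"
            )
        return SensingMatrix(self.entries / norms, self.row_ids, self.col_ids, True)

    def write_mtx(self, prefix) -> None:
        """Matrix Market coordinate file plus row/col id sidecar TSVs."""
        scipy.io.mmwrite(f"{prefix}.mtx", scipy.sparse.coo_matrix(self.entries))
        for suffix, ids in (("rows", self.row_ids), ("cols", self.col_ids)):
            with open(f"{prefix}.{suffix}.tsv", "w") as fh:
                fh.write("\n".join(ids) + "\n")

    def write_sif(self, path) -> None:
        """SIF edge list (motif 'kd' gene) for graph viewers."""
        with open(path, "w") as fh:
            for i, rid in enumerate(self.row_ids):
                for j, cid in enumerate(self.col_ids):
                    if self.entries[i, j] != 0:
                        fh.write(f"{rid}\tkd\t{cid}\n")


def build_sensing_matrix(profiles: list[MotifProfile], normalize: bool = True) -> SensingMatrix:
    """Assemble Phi from pruned profiles.

    Phi[i, j] is the percent identity between motif i's MCS and its
    occurrence site on gene j (the best site if several), 0 where motif i
    does not hit gene j. Columns are then scaled to unit l2 norm — the
    normalization compressed-sensing recovery guarantees assume.
    """
    if not profiles:
        raise ValueError("no profiles")
    row_ids = [p.motif_id for p in profiles]
    col_ids = sorted({g for p in profiles for g in p.gene_ids})
    col_index = {g: j for j, g in enumerate(col_ids)}
    entries = np.zeros((len(row_ids), len(col_ids)))
    for i, p in enumerate(profiles):
        for occ in p.occurrences:
            val = percent_identity(p.mcs, occ.site)
            j = col_index[occ.gene_id]
            entries[i, j] = max(entries[i, j], val)
    matrix = SensingMatrix(entries, row_ids, col_ids, normalized=False)
    return matrix.normalize_columns() if normalize else matrix


@dataclass
class CoherenceReport:
    """Pairwise column inner-product summary of a unit-norm matrix."""

    m_phi: float
    pair_count: int
    histogram: np.ndarray  # counts per bin of width 0.1 over [0, 1]
    zero_pairs: int


def coherence_report(matrix: SensingMatrix) -> CoherenceReport:
    """All n(n-1)/2 absolute column inner products, their max and histogram.

    The mutual coherence M_Phi is the largest absolute inner product between
    distinct columns; the smaller it is, the closer the columns are to an
    orthonormal system and the better sparse recovery behaves.
    """
    if not matrix.normalized:
        raise ValueError("normalize the matrix before computing coherence")
    gram = matrix.entries.T @ matrix.entries
    n = gram.shape[0]
    iu = np.triu_indices(n, k=1)
    products = np.abs(gram[iu])
    hist, _ = np.histogram(products, bins=np.arange(0.0, 1.1, 0.1))
    return CoherenceReport(
        m_phi=float(products.max()) if products.size else 0.0,
        pair_count=n * (n - 1) // 2,
        histogram=hist,
        zero_pairs=int(np.sum(products == 0.0)),
    )


@dataclass
class RIPEstimate:
    """Empirical restricted-isometry constant for subsets of size <= S."""

    S: int
    delta_S: float


def rip_delta(matrix: SensingMatrix, S: int, budget: int = 10 ** 6) -> RIPEstimate:
    """Exhaustive S-restricted isometry constant of a unit-norm matrix.

    delta_S is the smallest constant with
    (1 - delta_S)|c|^2 <= |Phi_T c|^2 <= (1 + delta_S)|c|^2 for every column
    subset T with |T| <= S — computed as the worst eigenvalue deviation of
    the subset Gram matrices from 1. Enumeration is guarded by ``budget``.
    """
    if not matrix.normalized:
        raise ValueError("normalize the matrix before estimating RIP constants")
    n = matrix.shape[1]
    if S < 1 or S > n:
        raise ValueError(f"S={S} outside 1..{n}")
    total = sum(math.comb(n, s) for s in range(1, S + 1))
    if total > budget:
        raise ValueError(
            f"{total} subsets exceed the enumeration budget {budget}; "
            "subsample columns or lower S"
        )
    gram = matrix.entries.T @ matrix.entries
    delta = 0.0
    for s in range(2, S + 1):  # singletons give delta 0 for unit-norm columns
        for subset in itertools.combinations(range(n), s):
            eig = np.linalg.eigvalsh(gram[np.ix_(subset, subset)])
            delta = max(delta, float(max(eig[-1] - 1.0, 1.0 - eig[0])))
    return RIPEstimate(S=S, delta_S=delta)
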