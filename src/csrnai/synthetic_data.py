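"""Synthetic fixtures with machine-readable ground truth.

Two generators make the whole pipeline testable without any external
download: motif-planted gene sets emulating a motif-discovery report over an
EST library, and activity-labeled siRNA tables generated from a planted,
recoverable position/thermodynamic rule emulating the structure of a large
published siRNA efficacy set. Both are bit-reproducible from their seed and
ship ground truth sufficient to compute expected downstream outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier_selection import LabeledRecord
from .motif_network import MOTIF_WIDTH
from .sequence_codec import SequenceSet
from .sirna_features import NNTable, load_nn_table

NUCLEOTIDES = "ACGT"


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    return "".join(rng.choice(list(NUCLEOTIDES), size=length, p=probs))


@dataclass
class PlantSpec:
    """Recipe for a motif-planted gene set."""

    n_genes: int
    gene_length_range: tuple[int, int] = (300, 600)
    gc_content: float = 0.5
    motifs: list[str] = field(default_factory=list)
    occurrence_map: dict[str, list[str]] = field(default_factory=dict)
    max_mismatches: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if self.max_mismatches > 5:
            raise ValueError("max_mismatches must be <= 5")
        for m in self.motifs:
            if len(m) != MOTIF_WIDTH:
                raise ValueError(f"motif {m!r} is not {MOTIF_WIDTH} nt")
        gene_ids = {f"g{i + 1}" for i in range(self.n_genes)}
        for motif_id, targets in self.occurrence_map.items():
            unknown = set(targets) - gene_ids
            if unknown:
                raise ValueError(f"{motif_id} targets unknown genes {sorted(unknown)}")


def _mutate(site: str, n_sub: int, rng: np.random.Generator) -> str:
    """Apply exactly n_sub substitutions at distinct random positions."""
    if n_sub == 0:
        return site
    positions = rng.choice(len(site), size=n_sub, replace=False)
    chars = list(site)
    for pos in positions:
        chars[pos] = rng.choice([nt for nt in NUCLEOTIDES if nt != chars[pos]])
    return "".join(chars)


def plant_motifs(spec: PlantSpec, mismatch_schedule=None):
    """Generate a gene set with motifs planted at known, collision-free sites.

    Genes are i.i.d. nucleotide strings at the requested GC content. For
    each (motif, gene) pair in the occurrence map, a copy of the motif with
    at most ``max_mismatches`` substitutions (uniform count unless a
    ``mismatch_schedule[(motif_id, gene_id)]`` pins it) is written at a
    random offset that does not overlap previously planted sites on that
    gene. Returns (SequenceSet, truth occurrence DataFrame); the pseudo
    p-value (mismatches+1)/(width+1) orders occurrences by match quality.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_length_range
    if lo < MOTIF_WIDTH:
        raise ValueError(f"genes must be at least {MOTIF_WIDTH} nt")
    gene_ids = [f"g{i + 1}" for i in range(spec.n_genes)]
    lengths = {g: int(rng.integers(lo, hi + 1)) for g in gene_ids}
    sequences = {g: list(_random_seq(lengths[g], spec.gc_content, rng)) for g in gene_ids}
    planted: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    rows = []
    motif_seq = {f"m{i + 1}": m for i, m in enumerate(spec.motifs)}
    for motif_id, motif in sorted(motif_seq.items()):
        for gene_id in spec.occurrence_map.get(motif_id, []):
            if mismatch_schedule and (motif_id, gene_id) in mismatch_schedule:
                n_sub = mismatch_schedule[(motif_id, gene_id)]
            else:
                n_sub = int(rng.integers(0, spec.max_mismatches + 1))
            site = _mutate(motif, n_sub, rng)
            start = _free_offset(lengths[gene_id], planted[gene_id], rng)
            planted[gene_id].append((start, start + MOTIF_WIDTH))
            sequences[gene_id][start : start + MOTIF_WIDTH] = list(site)
            rows.append(
                {
                    "motif_id": motif_id,
                    "gene_id": gene_id,
                    "start": start,
                    "site": site,
                    "p_value": (n_sub + 1) / (MOTIF_WIDTH + 1),
                }
            )
    seqset = SequenceSet(ids=gene_ids,
                         sequences=["".join(sequences[g]) for g in gene_ids])
    truth = pd.DataFrame(rows, columns=["motif_id", "gene_id", "start", "site", "p_value"])
    return seqset, truth


def _free_offset(length: int, taken: list[tuple[int, int]],
                 rng: np.random.Generator, tries: int = 200) -> int:
    if length < MOTIF_WIDTH:
        raise ValueError("gene too short to host a site")
    for _ in range(tries):
        start = int(rng.integers(0, length - MOTIF_WIDTH + 1))
        end = start + MOTIF_WIDTH
        if all(end <= s or start >= e for s, e in taken):
            return start
    raise ValueError("could not place a collision-free site; gene too crowded")


# ---------------------------------------------------------------------------
# Activity-labeled siRNA records from a planted rule
# ---------------------------------------------------------------------------

@dataclass
class ActivityRuleSpec:
    """Planted generative rule for siRNA interference activities.

    activity = logistic(sum of position-term weights + thermo_weight * duplex
    dG + N(0, noise_sd)), centered analytically at the rule's expectation
    under uniform random 19-mers so activities straddle 0.5.
    """

    psf_terms: list[tuple[int, str, float]] = field(default_factory=list)
    thermo_weight: float = 0.0
    noise_sd: float = 0.5
    n_records: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for pos, nt, _ in self.psf_terms:
            if not 1 <= pos <= 19 or nt not in NUCLEOTIDES:
                raise ValueError(f"invalid psf term ({pos}, {nt})")

    def expected_score(self, nn: NNTable) -> float:
        """Analytic mean of the raw score under uniform random 19-mers."""
        mean_stack = float(np.mean(list(nn.stack_dG.values())))
        e_thermo = self.thermo_weight * (18.0 * mean_stack + nn.initiation_dG)
        e_psf = sum(w / 4.0 for _, _, w in self.psf_terms)
        return e_psf + e_thermo

    def to_json(self) -> str:
        return json.dumps(
            {
                "psf_terms": self.psf_terms,
                "thermo_weight": self.thermo_weight,
                "noise_sd": self.noise_sd,
                "n_records": self.n_records,
                "seed": self.seed,
            }
        )


def synth_sirna_activity(spec: ActivityRuleSpec, nn: NNTable | None = None):
    """Generate activity-labeled random 19-mers from the planted rule.

    Returns (records, spec) where records is a list of
    :class:`~csrnai.classifier_selection.LabeledRecord` with activities in
    [0, 1] (labels unassigned; threshold them with ``make_datasets``).
    Noise is additive on the logit scale, so no truncation artifacts.
    """
    nn = nn or load_nn_table()
    rng = np.random.default_rng(spec.seed)
    center = spec.expected_score(nn)
    records = []
    for i in range(spec.n_records):
        seq = "".join(rng.choice(list(NUCLEOTIDES), size=19))
        score = sum(w for pos, nt, w in spec.psf_terms if seq[pos - 1] == nt)
        if spec.thermo_weight != 0.0:
            dg = sum(nn.stack_dG[seq[j : j + 2]] for j in range(18)) + nn.initiation_dG
            score += spec.thermo_weight * dg
        if spec.noise_sd > 0:
            score += rng.normal(0.0, spec.noise_sd)
        activity = 1.0 / (1.0 + math.exp(-(score - center)))
        records.append(LabeledRecord(f"s{i + 1}", seq, activity))
    return records, spec


# ---------------------------------------------------------------------------
# Paper-scale network fixture
# ---------------------------------------------------------------------------

def paper_scale_fixture(seed: int = 0, n_motifs: int = 48, n_genes: int = 146,
                        n_perfect: int = 6, n_degraded: int = 3,
                        degraded_mismatches: int = 5):
    """A screening-scale occurrence fixture: 48 motifs x 146 genes.

    Each motif hits ``n_perfect + n_degraded`` distinct genes: the perfect
    sites match the motif exactly (percent identity 1) and the degraded
    sites carry ``degraded_mismatches`` substitutions (identity 14/19 at the
    default). Targets are dealt least-covered-first, so the 48*9 = 432
    assignments spread to 2-3 motifs per gene and every gene is covered.
    Returns (SequenceSet, truth DataFrame).
    """
    rng = np.random.default_rng(seed)
    motifs = [_random_seq(MOTIF_WIDTH, 0.5, rng) for _ in range(n_motifs)]
    per_motif = n_perfect + n_degraded
    gene_ids = [f"g{i + 1}" for i in range(n_genes)]
    coverage = dict.fromkeys(gene_ids, 0)
    occurrence_map: dict[str, list[str]] = {}
    for i in range(n_motifs):
        jitter = {g: rng.random() for g in gene_ids}
        targets = sorted(gene_ids, key=lambda g: (coverage[g], jitter[g]))[:per_motif]
        for g in targets:
            coverage[g] += 1
        occurrence_map[f"m{i + 1}"] = targets
    schedule = {}
    for motif_id, targets in occurrence_map.items():
        for j, gene_id in enumerate(targets):
            schedule[(motif_id, gene_id)] = 0 if j < n_perfect else degraded_mismatches
    spec = PlantSpec(
        n_genes=n_genes,
        gene_length_range=(400, 600),
        gc_content=0.5,
        motifs=motifs,
        occurrence_map=occurrence_map,
        max_mismatches=5,
        seed=seed,
    )
    return plant_motifs(spec, mismatch_schedule=schedule)
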