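"""Occurrence ingest, consensus, pruning, sensing matrix and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from csrnai import (
    MotifOccurrence,
    MotifProfile,
    SensingMatrix,
    build_sensing_matrix,
    coherence_report,
    compute_mcs,
    percent_identity,
    prune_network,
    read_occurrences,
    rip_delta,
)

W = 19
A19 = "A" * W


def occ(motif, gene, site, start=0, p=0.05):
    return MotifOccurrence(motif, gene, start, site, p)


def profile(motif, sites_by_gene):
    return MotifProfile(motif, [occ(motif, g, s) for g, s in sites_by_gene.items()])


def table(rows):
    return pd.DataFrame(rows, columns=["motif_id", "gene_id", "start", "site", "p_value"])


class TestReadOccurrences:
    def test_groups_nine_targets_into_one_profile(self):
        rows = [("m1", f"g{i}", 0, A19, 0.01 * (i + 1)) for i in range(9)]
        profiles = read_occurrences(table(rows))
        assert len(profiles) == 1 and len(profiles[0].occurrences) == 9
        ps = [o.p_value for o in profiles[0].occurrences]
        assert ps == sorted(ps)

    def test_empty_table_gives_empty_list(self):
        assert read_occurrences(table([])) == []

    def test_duplicates_deduplicated(self, caplog):
        rows = [("m1", "g1", 0, A19, 0.01)] * 3 + [("m1", "g2", 5, A19, 0.02)]
        with caplog.at_level("WARNING", logger="csrnai"):
            profiles = read_occurrences(table(rows))
        assert len(profiles[0].occurrences) == 2

    def test_wrong_site_length_names_record(self):
        with pytest.raises(ValueError, match="m1.*length"):
            read_occurrences(table([("m1", "g1", 0, "ACGT", 0.01)]))


class TestMcs:
    def test_single_occurrence_is_itself(self):
        p = MotifProfile("m", [occ("m", "g1", A19)])
        assert p.mcs == A19

    def test_majority_vote(self):
        sites = ["AAG" + "A" * 16, "AAG" + "A" * 16, "ACG" + "A" * 16]
        p = MotifProfile("m", [occ("m", f"g{i}", s) for i, s in enumerate(sites)])
        assert p.mcs[1] == "A"

    def test_tie_breaks_lexicographically(self):
        p = MotifProfile("m", [occ("m", "g1", "G" * W), occ("m", "g2", "T" * W)])
        assert compute_mcs(p) == "G" * W
        q = MotifProfile("m", [occ("m", "g1", "C" * W), occ("m", "g2", "A" * W)])
        assert compute_mcs(q) == A19


class TestPercentIdentity:
    def test_bounds_and_fourteen_nineteenths(self):
        assert percent_identity(A19, A19) == 1.0
        site = "C" * 5 + "A" * 14
        assert percent_identity(A19, site) == pytest.approx(14 / 19)
        assert percent_identity(A19, "C" * W) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("ACG", "ACGT")


def _diverse_site(rng):
    return "".join(rng.choice(list("ACGT"), size=W, p=[0.3, 0.25, 0.25, 0.2]))


class TestPrune:
    def _network(self, seed=0):
        rng = np.random.default_rng(seed)
        s1, s2, s3 = (_diverse_site(rng) for _ in range(3))
        return [
            profile("m1", {"g1": s1, "g2": s1, "g3": s1}),
            profile("m2", {"g2": s2, "g3": s2, "g4": s2}),
            profile("m3", {"g1": s3, "g3": s3, "g4": s3}),
        ]

    def test_distinct_network_unchanged(self):
        net = self._network()
        pruned, audit = prune_network(net, seed=1)
        assert [p.motif_id for p in pruned] == ["m1", "m2", "m3"]
        assert audit.lines == []

    def test_one_to_one_pair_dropped(self):
        rng = np.random.default_rng(4)
        net = self._network() + [profile("m164", {"g541": _diverse_site(rng)})]
        pruned, audit = prune_network(net, seed=0)
        assert "m164" not in [p.motif_id for p in pruned]
        assert any("1-to-1" in line for line in audit.lines)

    def test_duplicate_signature_collapsed_deterministically(self):
        rng = np.random.default_rng(8)
        s1, s2 = _diverse_site(rng), _diverse_site(rng)
        net = [
            profile("m1", {"g1": s1, "g2": s1, "g3": s1}),
            profile("m2", {"g1": s2, "g2": s2, "g4": s2}),
        ]
        # g1 and g2 share the signature {m1, m2}: exactly one survives
        first, _ = prune_network(net, seed=3)
        genes = {g for p in first for g in p.gene_ids}
        assert len(genes & {"g1", "g2"}) == 1
        again, _ = prune_network(net, seed=3)
        assert {g for p in again for g in p.gene_ids} == genes

    def test_low_complexity_mcs_dropped(self):
        net = self._network() + [
            profile("mLC", {"g1": "A" * 16 + "CGT", "g2": "A" * 16 + "CGT"})
        ]
        pruned, audit = prune_network(net, seed=0)
        assert "mLC" not in [p.motif_id for p in pruned]
        assert any("low-complexity" in line for line in audit.lines)

    def test_idempotent(self):
        pruned, _ = prune_network(self._network(), seed=2)
        twice, _ = prune_network(pruned, seed=2)
        assert [(p.motif_id, sorted(p.gene_ids)) for p in twice] == [
            (p.motif_id, sorted(p.gene_ids)) for p in pruned
        ]


class TestSensingMatrix:
    def test_worked_example_row_values(self):
        rng = np.random.default_rng(0)
        mcs = _diverse_site(rng)
        degraded = "".join(
            ("A" if c != "A" else "C") if i < 5 else c for i, c in enumerate(mcs)
        )
        sites = {f"g{i}": mcs for i in range(6)} | {f"h{i}": degraded for i in range(3)}
        prof = MotifProfile("m200", [occ("m200", g, s) for g, s in sites.items()])
        assert prof.mcs == mcs  # 6-vs-3 majority at every position
        raw = build_sensing_matrix([prof], normalize=False)
        vals = sorted(raw.entries[0])
        assert vals[:3] == [pytest.approx(14 / 19)] * 3
        assert vals[3:] == [pytest.approx(1.0)] * 6

    def test_normalized_columns_unit_norm(self):
        rng = np.random.default_rng(1)
        profs = [
            profile("m1", {"g1": _diverse_site(rng), "g2": _diverse_site(rng)}),
            profile("m2", {"g1": _diverse_site(rng), "g3": _diverse_site(rng)}),
        ]
        mat = build_sensing_matrix(profs)
        assert mat.normalized
        assert np.allclose(np.linalg.norm(mat.entries, axis=0), 1.0, atol=1e-12)

    def test_exclusive_perfect_match_gives_coordinate_column(self):
        rng = np.random.default_rng(2)
        site = _diverse_site(rng)
        mat = build_sensing_matrix([profile("m1", {"g1": site})])
        assert np.allclose(mat.entries, [[1.0]])

    def test_occurrences_map_to_nonzeros(self):
        rng = np.random.default_rng(3)
        profs = [
            profile("m1", {"g1": _diverse_site(rng), "g2": _diverse_site(rng)}),
            profile("m2", {"g2": _diverse_site(rng)}),
        ]
        mat = build_sensing_matrix(profs, normalize=False)
        expected = {("m1", "g1"), ("m1", "g2"), ("m2", "g2")}
        nz = {
            (mat.row_ids[i], mat.col_ids[j])
            for i, j in zip(*np.nonzero(mat.entries))
        }
        assert nz == expected

    def test_mtx_round_trip(self, tmp_path):
        import scipy.io

        rng = np.random.default_rng(4)
        mat = build_sensing_matrix(
            [profile("m1", {"g1": _diverse_site(rng), "g2": _diverse_site(rng)})]
        )
        prefix = tmp_path / "phi"
        mat.write_mtx(str(prefix))
        back = scipy.io.mmread(f"{prefix}.mtx").toarray()
        assert np.allclose(back, mat.entries)


def _unit_matrix(entries):
    entries = np.asarray(entries, dtype=float)
    entries = entries / np.linalg.norm(entries, axis=0)
    m, n = entries.shape
    return SensingMatrix(entries, [f"r{i}" for i in range(m)],
                         [f"c{j}" for j in range(n)], normalized=True)


class TestCoherence:
    def test_pair_count_closed_form(self):
        rng = np.random.default_rng(0)
        mat = _unit_matrix(rng.normal(size=(4, 9)))
        assert coherence_report(mat).pair_count == 9 * 8 // 2

    def test_orthonormal_columns_zero_coherence(self):
        assert coherence_report(_unit_matrix(np.eye(5))).m_phi == 0.0

    def test_duplicated_column_full_coherence(self):
        e = np.eye(4)[:, :3]
        e = np.hstack([e, e[:, [0]]])
        assert coherence_report(_unit_matrix(e)).m_phi == pytest.approx(1.0)

    def test_unnormalized_rejected(self):
        mat = _unit_matrix(np.eye(3))
        mat.normalized = False
        with pytest.raises(ValueError):
            coherence_report(mat)


class TestRip:
    def test_orthonormal_columns_are_isometric(self):
        mat = _unit_matrix(np.eye(6))
        for s in (1, 2, 3):
            assert rip_delta(mat, s).delta_S == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_subset_size(self):
        rng = np.random.default_rng(5)
        mat = _unit_matrix(rng.normal(size=(6, 8)))
        deltas = [rip_delta(mat, s).delta_S for s in (2, 3, 4)]
        assert deltas == sorted(deltas)

    def test_delta2_closed_form_from_pairs(self):
        rng = np.random.default_rng(6)
        mat = _unit_matrix(rng.normal(size=(6, 8)))
        gram = mat.entries.T @ mat.entries
        iu = np.triu_indices(8, k=1)
        assert rip_delta(mat, 2).delta_S == pytest.approx(np.abs(gram[iu]).max(), abs=1e-12)

    def test_budget_guard(self):
        rng = np.random.default_rng(7)
        mat = _unit_matrix(rng.normal(size=(6, 12)))
        with pytest.raises(ValueError, match="budget"):
            rip_delta(mat, 6, budget=10)
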