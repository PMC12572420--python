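import numpy as np
import pandas as pd
import pytest

from crossgwas.loci import (
    ClumpParams,
    KnownLocusDB,
    LdMatrix,
    build_known_db,
    ld_clump,
    screen_novel,
)


def _records(rows):
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p"])


def brute_force_clump(records, ld, params):
    """Independent O(n^2) audit oracle: walk by ascending p and test every
    previously accepted SNP pairwise against the joint (distance, r2) rule."""
    df = records[records["p"] < params.p_threshold]
    df = df.sort_values(["p", "snp"], kind="mergesort")
    window = params.window_kb * 1000.0
    accepted = []
    for row in df.itertuples(index=False):
        excluded = False
        for acc in accepted:
            if (acc.chrom == row.chrom
                    and abs(acc.pos - row.pos) <= window
                    and ld.get(acc.snp, row.snp) >= params.r2_threshold):
                excluded = True
                break
        if not excluded:
            accepted.append(row)
    return [a.snp for a in accepted]


class TestLdMatrix:
    def test_symmetry_unit_diagonal_and_default_zero(self):
        m = LdMatrix({("a", "b"): 0.5})
        assert m.get("a", "b") == m.get("b", "a") == 0.5
        assert m.get("a", "a") == 1.0
        assert m.get("a", "zzz") == 0.0

    def test_table_round_trip(self):
        m = LdMatrix({("a", "b"): 0.5, ("b", "c"): 0.2})
        again = LdMatrix.from_table(m.to_table())
        assert again.get("a", "b") == 0.5 and again.get("c", "b") == 0.2

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValueError):
            LdMatrix({("a", "b"): 1.5})


class TestLdClump:
    PARAMS = ClumpParams(r2_threshold=0.001, window_kb=10_000, p_threshold=5e-6)

    def test_correlated_neighbour_clumped_away(self):
        recs = _records([("A", "1", 1_000_000, 1e-8),
                         ("B", "1", 1_100_000, 1e-7)])
        ld = LdMatrix({("A", "B"): 0.5})
        assert [iv.snp_id for iv in ld_clump(recs, ld, self.PARAMS)] == ["A"]

    def test_sub_threshold_r2_keeps_both(self):
        recs = _records([("A", "1", 1_000_000, 1e-8),
                         ("C", "1", 1_100_000, 1e-6)])
        ld = LdMatrix({("A", "C"): 0.0005})
        out = [iv.snp_id for iv in ld_clump(recs, ld, self.PARAMS)]
        assert out == ["A", "C"]

    def test_nothing_below_p_threshold_gives_empty(self):
        recs = _records([("A", "1", 100, 1e-3), ("B", "1", 200, 0.5)])
        assert ld_clump(recs, LdMatrix(), self.PARAMS) == []

    def test_distant_correlated_snp_survives(self):
        # correlated but outside the window: the joint rule keeps it
        recs = _records([("A", "1", 1_000_000, 1e-8),
                         ("B", "1", 1_000_000 + 10_001_000, 1e-7)])
        ld = LdMatrix({("A", "B"): 0.9})
        out = [iv.snp_id for iv in ld_clump(recs, ld, self.PARAMS)]
        assert out == ["A", "B"]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(21)
        for trial in range(60):
            n = int(rng.integers(2, 13))
            snps = [f"s{i}" for i in range(n)]
            recs = _records([
                (s, str(rng.integers(1, 3)), int(rng.integers(1, 4) * 400_000),
                 float(10 ** -rng.uniform(4, 10)))
                for s in snps])
            ld = LdMatrix()
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        ld.set(snps[i], snps[j], float(rng.random()))
            params = ClumpParams(r2_threshold=float(rng.choice([0.001, 0.1, 0.5])),
                                 window_kb=float(rng.choice([300, 1000])),
                                 p_threshold=1e-5)
            got = [iv.snp_id for iv in ld_clump(recs, ld, params)]
            assert got == brute_force_clump(recs, ld, params)

    def test_accepted_set_is_antichain(self):
        rng = np.random.default_rng(5)
        snps = [f"s{i}" for i in range(12)]
        recs = _records([(s, "1", int(rng.integers(1, 20) * 100_000),
                          float(10 ** -rng.uniform(6, 9))) for s in snps])
        ld = LdMatrix()
        for i in range(12):
            for j in range(i + 1, 12):
                ld.set(snps[i], snps[j], float(rng.random()))
        params = ClumpParams(r2_threshold=0.2, window_kb=500, p_threshold=1e-5)
        out = ld_clump(recs, ld, params)
        for a in out:
            for b in out:
                if a.snp_id != b.snp_id and a.chrom == b.chrom:
                    near = abs(a.pos - b.pos) <= params.window_kb * 1000
                    linked = ld.get(a.snp_id, b.snp_id) >= params.r2_threshold
                    assert not (near and linked)


class TestKnownDb:
    def test_single_suggestive_snp_single_entry(self):
        recs = _records([("A", "1", 1_000_000, 1e-7)])
        db = build_known_db({"s1": recs}, LdMatrix())
        assert len(db.entries) == 1
        assert db.nearest_distance("1", 1_000_000) == 0

    def test_shared_index_snp_collapses(self):
        recs = _records([("A", "1", 1_000_000, 1e-7)])
        db = build_known_db({"s1": recs, "s2": recs.copy()}, LdMatrix())
        assert len(db.entries) == 1
        assert db.entries.iloc[0]["source_study"] == "s1,s2"

    def test_three_disjoint_loci_three_entries(self):
        s1 = _records([("A", "1", 1_000_000, 1e-7),
                       ("B", "2", 5_000_000, 1e-8)])
        s2 = _records([("C", "3", 9_000_000, 1e-9)])
        db = build_known_db({"s1": s1, "s2": s2}, LdMatrix())
        assert len(db.entries) == 3

    def test_table_round_trip(self):
        s1 = _records([("A", "1", 1_000_000, 1e-7)])
        db = build_known_db({"s1": s1}, LdMatrix())
        again = KnownLocusDB.from_table(db.to_table())
        assert again.nearest_distance("1", 1_500_000) == 500_000


class TestScreenNovel:
    DB = KnownLocusDB(entries=pd.DataFrame(
        [("1", 1_000_000, "known1", "s1")],
        columns=["chrom", "pos", "snp", "source_study"]))

    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "p"])

    def test_hit_within_window_excluded(self):
        hits = self._hits([("h1", "1", 1_400_000, 1e-9)])
        assert len(screen_novel(hits, self.DB)) == 0

    def test_boundary_distance_is_novel(self):
        hits = self._hits([("h1", "1", 1_500_000, 1e-9)])
        out = screen_novel(hits, self.DB)
        assert list(out["snp"]) == ["h1"]

    def test_absent_chromosome_is_novel(self):
        hits = self._hits([("h2", "2", 1_000_000, 1e-9)])
        assert list(screen_novel(hits, self.DB)["snp"]) == ["h2"]

    def test_non_significant_hits_never_screened_in(self):
        hits = self._hits([("h3", "2", 1_000_000, 1e-6)])
        assert len(screen_novel(hits, self.DB, p_threshold=5e-8)) == 0

    def test_monotone_in_min_distance(self):
        rng = np.random.default_rng(9)
        hits = self._hits([(f"h{i}", "1", int(rng.integers(1, 40) * 100_000),
                            1e-9) for i in range(30)])
        prev = None
        for dist in (100, 300, 500, 900):
            cur = set(screen_novel(hits, self.DB, min_dist_kb=dist)["snp"])
            if prev is not None:
                assert cur <= prev
            prev = cur
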