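import numpy as np
import pytest

from seqloop.odh import ODHConfig, kmer_index
from seqloop.svm import SparseWeightVector
from seqloop.viz import (
    ampd,
    pwwm,
    pwwms_from_selection,
    render_ampd,
    render_topn,
    topn,
    write_ampd_tsv,
    write_topn_tsv,
)


def weight_from_entries(cfg, entries):
    """entries: list of (left_kmer, right_kmer, d, value)."""
    keys = [cfg.key(kmer_index(l, cfg), kmer_index(r, cfg), d) for l, r, d, _ in entries]
    vals = [v for _, _, _, v in entries]
    return SparseWeightVector(config=cfg, keys=np.array(keys), values=np.array(vals))


def random_weight(cfg, rng, n):
    keys = rng.choice(cfg.dimension, size=n, replace=False)
    vals = rng.standard_normal(n)
    return SparseWeightVector(config=cfg, keys=keys, values=vals)


class TestAMPD:
    def test_single_entry(self):
        cfg = ODHConfig(K=3, D=20)
        w = weight_from_entries(cfg, [("ACG", "TGA", 12, 0.7)])
        t = ampd(w, cfg)
        assert t.positive[12].pair == "ACG|TGA"
        assert t.positive[12].weight == pytest.approx(0.7)
        assert t.negative[12].weight == 0.0

    def test_all_zero_vector_reports_lexicographic_first_pair(self):
        cfg = ODHConfig(K=2, D=5)
        w = SparseWeightVector(config=cfg, keys=np.array([], dtype=int), values=np.array([]))
        t = ampd(w, cfg)
        for d in range(6):
            assert t.positive[d].pair == "AA|AA" and t.positive[d].weight == 0.0
            assert t.negative[d].pair == "AA|AA" and t.negative[d].weight == 0.0

    def test_matches_exhaustive_scan_oracle(self):
        cfg = ODHConfig(K=1, D=5)  # 16 pairs x 6 distances: exhaustible
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, cfg.dimension))
            w = random_weight(cfg, rng, n)
            dense = np.zeros(cfg.dimension)
            dense[w.keys] = w.values
            t = ampd(w, cfg)
            for d in range(cfg.D + 1):
                col = dense[d :: cfg.D + 1]  # all pairs at distance d, pair-index order
                best_pos = max(col.max(), 0.0)
                best_neg = min(col.min(), 0.0)
                assert t.positive[d].weight == pytest.approx(best_pos)
                assert t.negative[d].weight == pytest.approx(best_neg)
                if best_pos > 0:  # ties break to the first pair index
                    assert np.argmax(col == best_pos) == _pair_index(t.positive[d].pair, cfg)

    def test_polarity_invariant(self):
        cfg = ODHConfig(K=1, D=3)
        rng = np.random.default_rng(5)
        t = ampd(random_weight(cfg, rng, 30), cfg)
        for p, n in zip(t.positive, t.negative):
            assert p.weight >= 0.0 >= n.weight


def _pair_index(pair: str, cfg) -> int:
    l, r = pair.split("|")
    return kmer_index(l, cfg) * cfg.n_kmers + kmer_index(r, cfg)


class TestTopN:
    def test_n1_is_global_extreme(self):
        cfg = ODHConfig(K=2, D=10)
        w = weight_from_entries(
            cfg, [("AC", "GT", 3, 0.5), ("CA", "TG", 7, 0.9), ("AA", "TT", 2, -1.4)]
        )
        sel = topn(w, N=1, polarity="positive")
        assert sel.entries == [(7, "CA|TG", pytest.approx(0.9))]
        neg = topn(w, N=1, polarity="negative")
        assert neg.entries[0][1] == "AA|TT"

    def test_request_exceeding_entries_takes_all(self, caplog):
        cfg = ODHConfig(K=2, D=10)
        w = weight_from_entries(cfg, [("AC", "GT", 3, 0.5)])
        sel = topn(w, N=25, polarity="positive")
        assert sel.N == 1

    def test_matches_sort_oracle(self):
        cfg = ODHConfig(K=2, D=20)
        rng = np.random.default_rng(2)
        for _ in range(20):
            w = random_weight(cfg, rng, 500)
            sel = topn(w, N=25, polarity="positive")
            oracle = sorted(w.values[w.values > 0], reverse=True)[:25]
            assert [v for _, _, v in sel.entries] == pytest.approx(oracle)
            assert sel.threshold == pytest.approx(oracle[-1])
            neg = topn(w, N=25, polarity="negative")
            neg_oracle = sorted(w.values[w.values < 0])[:25]
            assert [v for _, _, v in neg.entries] == pytest.approx(neg_oracle)


class TestPWWM:
    def test_three_motif_weighted_stack(self):
        # motifs AAA|GAA, GAA|AGA, AAG|AAA with magnitudes 1, 2, 3; total 6.
        # Computed per the stacking rule by hand, column by column.
        p = pwwm([("AAA|GAA", 1.0), ("GAA|AGA", 2.0), ("AAG|AAA", 3.0)], K=3)
        A, C, G, T = p.matrix
        assert A[0] == pytest.approx(4 / 6) and G[0] == pytest.approx(2 / 6)
        assert A[1] == pytest.approx(1.0)
        assert A[2] == pytest.approx(3 / 6) and G[2] == pytest.approx(3 / 6)
        assert A[3] == pytest.approx(5 / 6) and G[3] == pytest.approx(1 / 6)
        assert A[4] == pytest.approx(4 / 6) and G[4] == pytest.approx(2 / 6)
        assert A[5] == pytest.approx(1.0)
        assert np.all(C == 0) and np.all(T == 0)
        assert p.normalizer == pytest.approx(6.0)

    def test_columns_sum_to_one_and_order_invariance(self):
        rng = np.random.default_rng(3)
        motifs = [
            ("".join(rng.choice(list("ACGT"), size=6)), float(rng.uniform(0.1, 2)))
            for _ in range(8)
        ]
        a = pwwm(motifs, K=3)
        b = pwwm(list(reversed(motifs)), K=3)
        assert np.allclose(a.matrix.sum(axis=0), 1.0, atol=1e-12)
        assert np.allclose(a.matrix, b.matrix)

    def test_single_motif_one_hot(self):
        p = pwwm([("ACGT", 0.5)], K=2)
        assert np.all(np.sort(p.matrix, axis=0)[-1] == 1.0)
        assert p.consensus() == "ACGT"

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            pwwm([("ACGT", 1.0), ("ACGTAA", 1.0)], K=2)

    def test_from_selection_groups_by_distance(self):
        cfg = ODHConfig(K=2, D=10)
        w = weight_from_entries(
            cfg, [("AC", "GT", 3, 0.5), ("CA", "TG", 3, 0.4), ("AA", "TT", 7, 0.3)]
        )
        sel = topn(w, N=3, polarity="positive")
        pws = pwwms_from_selection(sel, K=2)
        assert set(pws) == {3, 7}
        assert pws[3].normalizer == pytest.approx(0.9)


class TestRendering:
    def _table_and_sel(self):
        cfg = ODHConfig(K=2, D=15)
        rng = np.random.default_rng(8)
        w = random_weight(cfg, rng, 120)
        return cfg, ampd(w, cfg), topn(w, N=10, polarity="positive")

    def test_ampd_render_smoke_and_determinism(self, tmp_path):
        cfg, table, _ = self._table_and_sel()
        p1, p2 = tmp_path / "a1.png", tmp_path / "a2.png"
        render_ampd(table, p1)
        render_ampd(table, p2)
        assert p1.stat().st_size > 0
        assert p1.read_bytes() == p2.read_bytes()

    def test_topn_render_smoke(self, tmp_path):
        cfg, _, sel = self._table_and_sel()
        pws = pwwms_from_selection(sel, K=2)
        out = tmp_path / "t.png"
        render_topn(sel, pws, out, D=cfg.D)
        assert out.stat().st_size > 0

    def test_empty_table_renders_without_crash(self, tmp_path):
        cfg = ODHConfig(K=2, D=5)
        w = SparseWeightVector(config=cfg, keys=np.array([], dtype=int), values=np.array([]))
        render_ampd(ampd(w, cfg), tmp_path / "empty.png")
        assert (tmp_path / "empty.png").stat().st_size > 0

    def test_tsv_dumps(self, tmp_path):
        cfg, table, sel = self._table_and_sel()
        write_ampd_tsv(tmp_path / "a.tsv", table)
        write_topn_tsv(tmp_path / "t.tsv", sel)
        assert len((tmp_path / "a.tsv").read_text().splitlines()) == cfg.D + 2
        assert len((tmp_path / "t.tsv").read_text().splitlines()) == sel.N + 2
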