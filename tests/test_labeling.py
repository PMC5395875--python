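import numpy as np
import pytest

from seqloop.genomic import GenomicLocus, PeakRecord, ReplicatePeakTable, SparseContactMatrix
from seqloop.labeling import (
    HiCValidationConfig,
    OEMatrix,
    binarize_contacts,
    distance_filter,
    hic_significant_partners,
    normalize_hic,
    observed_expected,
)


def make_table(calls: dict[str, tuple[bool, ...]], col="model", fdr=10.0):
    """calls: row_id -> per-replicate called flags."""
    recs = []
    for row, flags in calls.items():
        for i, f in enumerate(flags):
            recs.append(PeakRecord(row, col, f"rep{i + 1}", f, fdr))
    return ReplicatePeakTable(recs)


class TestBinarize:
    def test_replicate_agreement_partition(self):
        t = make_table(
            {
                "both": (True, True),
                "one": (True, False),
                "other": (False, True),
                "none": (False, False),
            }
        )
        ls = binarize_contacts(t, "model", 10.0)
        assert ls.positives == ["both"]
        assert ls.negatives == ["none"]
        assert sorted(ls.uncalled) == ["one", "other"]
        assert ls.n_tested == 4

    def test_counts_match_replicate_structure_at_scale(self):
        # 30 all-replicate calls and 201 zero-replicate calls
        calls = {f"p{i}": (True, True) for i in range(30)}
        calls.update({f"n{i}": (False, False) for i in range(201)})
        ls = binarize_contacts(make_table(calls), "model", 10.0)
        assert (len(ls.positives), len(ls.negatives)) == (30, 201)
        assert ls.uncalled == []

    def test_missing_model_locus_errors(self):
        t = make_table({"a": (True, True)})
        with pytest.raises(ValueError, match="absent"):
            binarize_contacts(t, "nope", 10.0)

    def test_pair_missing_in_a_replicate_goes_uncalled(self):
        recs = [
            PeakRecord("a", "model", "rep1", True, 10.0),
            PeakRecord("a", "model", "rep2", True, 10.0),
            PeakRecord("b", "model", "rep1", True, 10.0),  # rep2 missing
        ]
        ls = binarize_contacts(ReplicatePeakTable(recs), "model", 10.0)
        assert ls.positives == ["a"]
        assert ls.uncalled == ["b"]


def full_matrix(vals: np.ndarray, resolution=5000, norm=None) -> SparseContactMatrix:
    """Dense symmetric matrix -> sparse storage including zero entries (so the
    bin span is explicit)."""
    n = vals.shape[0]
    ii, jj = np.triu_indices(n)
    return SparseContactMatrix(
        resolution=resolution,
        chrom="chrT",
        bin_i=ii * resolution,
        bin_j=jj * resolution,
        counts=vals[ii, jj],
        norm_vector=np.ones(n) if norm is None else norm,
    )


class TestNormalize:
    def test_identity_norm_leaves_counts(self):
        m = full_matrix(np.full((3, 3), 4.0))
        out = normalize_hic(m)
        assert np.allclose(out.counts, m.counts)

    def test_factor_arithmetic(self):
        m = SparseContactMatrix(
            resolution=5000, chrom="c", bin_i=[0], bin_j=[5000], counts=[12],
            norm_vector=np.array([2.0, 3.0]),
        )
        assert normalize_hic(m).counts[0] == pytest.approx(2.0)

    def test_nan_factor_drops_touching_entries(self):
        m = SparseContactMatrix(
            resolution=5000, chrom="c",
            bin_i=[0, 0, 5000], bin_j=[5000, 10000, 10000], counts=[1, 2, 3],
            norm_vector=np.array([np.nan, 1.0, 1.0]),
        )
        out = normalize_hic(m)
        assert out.n_entries == 1
        assert (out.bin_i[0], out.bin_j[0]) == (5000, 10000)

    def test_missing_norm_vector_errors(self):
        m = SparseContactMatrix(resolution=5000, chrom="c", bin_i=[0], bin_j=[0], counts=[1])
        with pytest.raises(ValueError, match="normalization"):
            normalize_hic(m)


class TestObservedExpected:
    def test_constant_matrix_gives_unit_oe(self):
        oe = observed_expected(full_matrix(np.full((5, 5), 7.0)))
        assert all(v == pytest.approx(1.0) for v in oe.oe.values())

    def test_single_nonzero_cell_oe_equals_pair_count(self):
        # 6 bins, one non-zero at distance 3: three pairs exist at d=3,
        # so expected = x/3 and O/E = 3
        vals = np.zeros((6, 6))
        vals[0, 3] = vals[3, 0] = 6.0
        oe = observed_expected(full_matrix(vals))
        assert oe.get(0, 3) == pytest.approx(3.0)

    def test_planted_enrichment_crosses_cutoff(self):
        vals = np.full((6, 6), 10.0)
        vals[1, 3] = vals[3, 1] = 50.0
        oe = observed_expected(full_matrix(vals))
        assert oe.get(1, 3) >= 2.5
        others = [v for k, v in oe.oe.items() if k != (1, 3)]
        assert max(others) < 2.5

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 5, (6, 6))
        vals = (vals + vals.T) / 2
        a = observed_expected(full_matrix(vals))
        b = observed_expected(full_matrix(vals * 37.0))
        for k in a.oe:
            assert a.oe[k] == pytest.approx(b.oe[k])


def oe_from_dict(d: dict, resolution: int) -> OEMatrix:
    return OEMatrix(resolution=resolution, chrom="chrT", oe=d, expected_profile=np.ones(1))


class TestSignificance:
    model = GenomicLocus("chrT", 0, 5000, "model")  # 5 kb bin 0

    def build(self, oe5, oe10, oe25, partner=4):
        c10 = partner // 2
        c25 = partner // 5
        return {
            5000: oe_from_dict({(0, partner): oe5}, 5000),
            10000: oe_from_dict({(0, c10): oe10}, 10000),
            25000: oe_from_dict({(0, c25): oe25}, 25000),
        }

    @pytest.mark.parametrize(
        "oe5,oe10,oe25,expected",
        [
            (3.0, 2.6, 1.0, True),   # confirmed at 10k
            (3.0, 2.0, 2.0, False),  # significant only at 5k -> rejected
            (2.5, 2.5, 0.0, True),   # cutoff is inclusive
            (2.0, 5.0, 5.0, False),  # must qualify at the primary resolution
        ],
    )
    def test_multi_resolution_rule(self, oe5, oe10, oe25, expected):
        sig, tested = hic_significant_partners(
            self.build(oe5, oe10, oe25), self.model, HiCValidationConfig()
        )
        assert tested == [4]
        assert (sig == [4]) is expected

    def test_missing_resolution_errors(self):
        oes = self.build(3.0, 3.0, 3.0)
        del oes[25000]
        with pytest.raises(ValueError, match="missing"):
            hic_significant_partners(oes, self.model, HiCValidationConfig())

    def test_multi_bin_model_locus_qualifies_via_any_column(self):
        # model locus spans 5 kb bins 0 and 1; partner qualifies against bin 1 only
        model = GenomicLocus("chrT", 0, 10000, "model")
        oes = {
            5000: oe_from_dict({(0, 8): 1.0, (1, 8): 3.0}, 5000),
            10000: oe_from_dict({(0, 4): 3.0}, 10000),
            25000: oe_from_dict({}, 25000),
        }
        sig, tested = hic_significant_partners(oes, model, HiCValidationConfig())
        assert sig == [8] and tested == [8]

    def test_monotone_in_cutoff(self):
        oes = self.build(3.0, 2.6, 1.0)
        got = set()
        for cutoff in (1.5, 2.5, 2.7, 3.5):
            sig, _ = hic_significant_partners(
                oes, self.model, HiCValidationConfig(oe_cutoff=cutoff)
            )
            got.add((cutoff, tuple(sig)))
        sizes = [len(s) for _, s in sorted(got)]
        assert sizes == sorted(sizes, reverse=True)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            HiCValidationConfig(oe_cutoff=0)
        with pytest.raises(ValueError):
            HiCValidationConfig(primary_resolution=25000)


class TestDistanceFilter:
    model = GenomicLocus("chrT", 10_000_000, 10_010_000, "m")

    def test_band_exclusion(self):
        near = 10_500_000 // 5000   # 0.5 Mb away
        far = 11_600_000 // 5000    # ~1.6 Mb away
        kept = distance_filter([near, far], self.model, 1_000_000, 5000)
        assert kept == [far]

    def test_zero_band_is_identity(self):
        bins = [0, 1, 2000, 2002]
        assert distance_filter(bins, self.model, 0, 5000) == bins
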