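import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6avote.exceptions import (
    ConfigError,
    DegeneratePropertyError,
    InsufficientLengthError,
    SequenceTooShortError,
)
from m6avote.psednc import (
    DINUCLEOTIDES,
    PropertyTable,
    PseDncConfig,
    builtin_property_table,
    dinucleotide_frequencies,
    encode_psednc,
    optimize_psednc_params,
    psednc_vector,
    standardize_properties,
    theta_correlation,
    tier_correlation_factors,
)


def _oracle_psednc(seq, lam, w, table):
    """Independent spreadsheet-style evaluation: plain-Python loops only."""
    dinucs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    f = [dinucs.count(d) / len(dinucs) for d in DINUCLEOTIDES]

    def theta_fn(a, b):
        pa, pb = table.row(a), table.row(b)
        return sum((x - y) ** 2 for x, y in zip(pa, pb)) / len(pa)

    thetas = []
    for j in range(1, lam + 1):
        pairs = [(dinucs[i], dinucs[i + j]) for i in range(len(dinucs) - j)]
        thetas.append(sum(theta_fn(a, b) for a, b in pairs) / len(pairs))
    denom = 1 + w * sum(thetas)
    return [x / denom for x in f] + [w * t / denom for t in thetas]


class TestPropertyTable:
    def test_builtin_rows_and_completeness(self):
        table = builtin_property_table()
        assert table.v == 3
        assert table.matrix.shape == (16, 3)
        assert tuple(table.row("GG")) == (-12.2, -29.7, -3.26)
        assert tuple(table.row("AU")) == (-5.7, -15.5, -1.10)

    def test_standardization_centers_and_scales(self):
        std = standardize_properties(builtin_property_table())
        assert std.standardized
        assert np.allclose(std.matrix.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(std.matrix.std(axis=0), 1.0, atol=1e-9)

    def test_identical_raw_rows_stay_identical(self, std_table):
        assert np.allclose(std_table.row("GG"), std_table.row("CC"))
        assert np.allclose(std_table.row("AC"), std_table.row("GU"))

    def test_zero_variance_column_rejected(self):
        table = PropertyTable(matrix=np.ones((16, 2)))
        with pytest.raises(DegeneratePropertyError):
            standardize_properties(table)

    def test_tsv_roundtrip(self, tmp_path):
        table = builtin_property_table()
        p = tmp_path / "props.tsv"
        table.to_tsv(p)
        back = PropertyTable.from_tsv(p)
        assert np.array_equal(back.matrix, table.matrix)


class TestThetaCorrelation:
    def test_zero_on_identical_dinucleotide(self, std_table):
        for d in DINUCLEOTIDES:
            assert theta_correlation(d, d, std_table) == 0.0

    def test_zero_on_identical_property_rows(self, std_table):
        assert theta_correlation("GG", "CC", std_table) == 0.0
        assert theta_correlation("AC", "GU", std_table) == 0.0

    def test_symmetric_nonnegative(self, std_table):
        for a in DINUCLEOTIDES[:4]:
            for b in DINUCLEOTIDES[::5]:
                t = theta_correlation(a, b, std_table)
                assert t >= 0.0
                assert t == theta_correlation(b, a, std_table)

    def test_requires_standardized_table(self):
        with pytest.raises(ConfigError):
            theta_correlation("AA", "AC", builtin_property_table())


class TestFrequencies:
    def test_homopolymer(self):
        f = dinucleotide_frequencies("A" * 51)
        assert f[DINUCLEOTIDES.index("AA")] == 1.0
        assert f.sum() == 1.0

    def test_overlapping_acgu(self):
        f = dinucleotide_frequencies("ACGU", "overlapping")
        expected = {"AC": 1 / 3, "CG": 1 / 3, "GU": 1 / 3}
        for d in DINUCLEOTIDES:
            assert f[DINUCLEOTIDES.index(d)] == pytest.approx(expected.get(d, 0.0))

    def test_nonoverlapping_acgu(self):
        f = dinucleotide_frequencies("ACGU", "nonoverlapping")
        expected = {"AC": 0.5, "GU": 0.5}
        for d in DINUCLEOTIDES:
            assert f[DINUCLEOTIDES.index(d)] == pytest.approx(expected.get(d, 0.0))

    def test_too_short(self):
        with pytest.raises(SequenceTooShortError):
            dinucleotide_frequencies("A")


class TestTierCorrelationFactors:
    def test_single_dinucleotide_species_gives_zero(self, std_table):
        assert np.all(tier_correlation_factors("G" * 6, 3, std_table) == 0.0)
        assert np.all(tier_correlation_factors("A" * 51, 6, std_table) == 0.0)

    def test_acgua_lambda2_hand_oracle(self, std_table):
        theta = tier_correlation_factors("ACGUA", 2, std_table)
        t = lambda a, b: theta_correlation(a, b, std_table)
        expected1 = (t("AC", "CG") + t("CG", "GU") + t("GU", "UA")) / 3
        expected2 = (t("AC", "GU") + t("CG", "UA")) / 2
        assert theta[0] == pytest.approx(expected1, abs=1e-12)
        assert theta[1] == pytest.approx(expected2, abs=1e-12)
        assert t("AC", "GU") == 0.0

    def test_lambda_too_large(self, std_table):
        with pytest.raises(InsufficientLengthError):
            tier_correlation_factors("ACGUA", 4, std_table)


class TestPseDncVector:
    def test_polya_is_unit_aa_component(self, std_table):
        v = psednc_vector("A" * 51, PseDncConfig(), std_table)
        expected = np.zeros(22)
        expected[0] = 1.0
        assert np.allclose(v.d, expected)

    def test_acgua_matches_independent_oracle(self, std_table):
        cfg = PseDncConfig(lam=2, w=0.9)
        v = psednc_vector("ACGUA", cfg, std_table)
        oracle = _oracle_psednc("ACGUA", 2, 0.9, std_table)
        assert np.allclose(v.d, oracle, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        seq=st.text(alphabet="ACGU", min_size=10, max_size=60),
        lam=st.integers(min_value=0, max_value=6),
        mode=st.sampled_from(["overlapping", "nonoverlapping"]),
    )
    def test_sum_to_one_and_nonnegative(self, std_table, seq, lam, mode):
        cfg = PseDncConfig(lam=lam, counting_mode=mode)
        v = psednc_vector(seq, cfg, std_table)
        assert v.d.shape == (16 + lam,)
        assert np.all(v.d >= 0)
        assert v.d.sum() == pytest.approx(1.0, abs=1e-9)

    def test_lambda0_reduces_to_plain_composition(self, std_table):
        seq = "ACGUACGUACGGUUA"
        v = psednc_vector(seq, PseDncConfig(lam=0), std_table)
        assert np.allclose(v.d, dinucleotide_frequencies(seq))

    def test_w0_keeps_raw_frequencies(self, std_table):
        seq = "ACGUACGUACGGUUA"
        v = psednc_vector(seq, PseDncConfig(lam=4, w=0.0), std_table)
        assert np.allclose(v.d[:16], dinucleotide_frequencies(seq))
        assert np.allclose(v.d[16:], 0.0)

    def test_scaling_thetas_shrinks_frequency_block(self, std_table):
        # A table with doubled property values scales every theta by 4,
        # strictly decreasing each of the first 16 components.
        seq = "ACGUACGUACGGUUA"
        big = PropertyTable(matrix=std_table.matrix * 2.0, standardized=True)
        v1 = psednc_vector(seq, PseDncConfig(lam=3), std_table)
        v2 = psednc_vector(seq, PseDncConfig(lam=3), big)
        assert np.allclose(v2.theta, 4.0 * v1.theta)
        nonzero = v1.d[:16] > 0
        assert np.all(v2.d[:16][nonzero] < v1.d[:16][nonzero])

    def test_encode_matrix_shape(self, std_table):
        X = encode_psednc(["ACGUACGUA", "GGGGCCCCA"], PseDncConfig(lam=3), std_table)
        assert X.shape == (2, 19)


class TestParamOptimization:
    def test_grid_search_returns_best_point(self, separable_dataset):
        residues = [w.residues for w in separable_dataset]
        labels = [1 if w.label == "m6A" else -1 for w in separable_dataset]
        w, lam, score = optimize_psednc_params(
            residues, labels, w_grid=[0.5, 0.9], lambda_grid=[1, 2], cv=2, seed=0
        )
        assert w in (0.5, 0.9)
        assert lam in (1, 2)
        assert 0.0 <= score <= 1.0


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [{"lam": -1}, {"w": 1.5}, {"counting_mode": "weird"}]
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            PseDncConfig(**kwargs)
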