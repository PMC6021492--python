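"""Synthetic-data generator tests: validation, determinism, recovery."""

import numpy as np
import pytest

from ifnsig import (
    CellCycleSimConfig,
    CohortSimConfig,
    MarkerSimConfig,
    gate_events,
    generate_cohort,
    generate_dna_content,
    generate_marker_tubes,
    geometric_mfi,
    quantify_fractions,
    relative_mfi,
)

from conftest import normalized_fractions


def _measured_rmfi(stained, fmo):
    return relative_mfi(
        geometric_mfi(gate_events(stained), "MARKER"),
        geometric_mfi(gate_events(fmo), "MARKER"),
    )


class TestMarkerTubes:
    def test_stained_equals_fmo_at_unit_ratio(self):
        cfg = MarkerSimConfig(true_relative_mfi=1.0, n_events=20_000, seed=0)
        stained, fmo = generate_marker_tubes(cfg)
        assert _measured_rmfi(stained, fmo) == pytest.approx(1.0, abs=0.02)

    def test_recovers_target_relative_mfi(self):
        # oracle: geometric means computed directly on the generated arrays
        cfg = MarkerSimConfig(true_relative_mfi=10.0, n_events=50_000, seed=1)
        stained, fmo = generate_marker_tubes(cfg)
        direct = (np.exp(np.mean(np.log(stained.data["MARKER"])))
                  / np.exp(np.mean(np.log(fmo.data["MARKER"]))))
        assert direct == pytest.approx(10.0, rel=0.05)
        assert _measured_rmfi(stained, fmo) == pytest.approx(10.0, rel=0.05)

    def test_bimodal_positive_fraction(self):
        cfg = MarkerSimConfig(true_relative_mfi=6.0, positive_fraction=0.5,
                              n_events=50_000, seed=2)
        stained, fmo = generate_marker_tubes(cfg)
        # oracle: count generated events above the FMO 99th percentile
        gate = np.quantile(fmo.data["MARKER"], 0.99)
        frac = np.mean(stained.data["MARKER"].to_numpy() > gate)
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_identical_metadata_except_tube_kind(self):
        stained, fmo = generate_marker_tubes(
            MarkerSimConfig(n_events=500, seed=3),
            line_id="X", marker="NGFR", condition="IFNg")
        assert stained.tube_kind == "stained" and fmo.tube_kind == "FMO"
        assert (stained.line_id, stained.marker, stained.condition) == \
               (fmo.line_id, fmo.marker, fmo.condition)

    def test_determinism(self):
        cfg = MarkerSimConfig(true_relative_mfi=3.0, n_events=1000, seed=11)
        a, _ = generate_marker_tubes(cfg)
        b, _ = generate_marker_tubes(cfg)
        assert a.data.equals(b.data)

    def test_scale_equivariance_of_relative_mfi(self):
        # shifting the log-location rescales both tubes, leaving the ratio
        base = MarkerSimConfig(true_relative_mfi=4.0, n_events=20_000, seed=5)
        shifted = MarkerSimConfig(true_relative_mfi=4.0, fmo_log_mean=3.0,
                                  n_events=20_000, seed=5)
        r1 = _measured_rmfi(*generate_marker_tubes(base))
        r2 = _measured_rmfi(*generate_marker_tubes(shifted))
        assert r1 == pytest.approx(r2, rel=1e-9)

    @pytest.mark.parametrize("kwargs, field", [
        (dict(n_events=50), "n_events"),
        (dict(fmo_log_sd=0.0), "fmo_log_sd"),
        (dict(positive_fraction=1.5), "positive_fraction"),
        (dict(true_relative_mfi=0.1), "true_relative_mfi"),
        (dict(dead_fraction=0.9), "dead_fraction"),
        (dict(doublet_fraction=0.5), "doublet_fraction"),
    ])
    def test_validation_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            generate_marker_tubes(MarkerSimConfig(**kwargs))


class TestDnaContent:
    def test_pure_g1(self):
        cfg = CellCycleSimConfig(fractions=(0, 100, 0, 0), n_events=20_000,
                                 seed=0)
        fr = quantify_fractions(generate_dna_content(cfg))
        assert fr.g1 == pytest.approx(100.0, abs=1.0)

    def test_recovers_published_profile(self):
        target = normalized_fractions((1.1, 69.9, 19.9, 10.2))
        cfg = CellCycleSimConfig(fractions=target, n_events=100_000, seed=7)
        fr = quantify_fractions(generate_dna_content(cfg))
        for got, want in zip((fr.subg1, fr.g1, fr.s, fr.g2), target):
            assert got == pytest.approx(want, abs=2.0)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="n_events"):
            generate_dna_content(CellCycleSimConfig(n_events=0))

    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError, match="sum to 100"):
            generate_dna_content(
                CellCycleSimConfig(fractions=(10, 60, 20, 20)))


class TestCohort:
    def test_default_structure_matches_panel(self):
        cfg = CohortSimConfig(n_events=150, seed=0)
        result = generate_cohort(cfg)
        assert len(result.truth) == 39
        sizes = result.truth["genotype"].value_counts().to_dict()
        assert sizes == {"BRAF": 11, "NRAS": 10, "WT": 10, "GNAQ/GNA11": 8}
        # every line x marker x condition has a stained and an FMO tube
        assert len(result.tubes) == 39 * 5 * 2 * 2

    def test_null_responder_defect_propagates(self):
        cfg = CohortSimConfig(
            group_sizes={"BRAF": 1, "NRAS": 0, "WT": 0, "GNAQ/GNA11": 0},
            n_events=150, seed=1, null_responder_fraction=1.0)
        truth = generate_cohort(cfg).truth
        assert truth["defect"].tolist() == ["null_responder"]
        assert truth["true_response_class"].tolist() == ["null"]

    def test_mhc1_loss_defect(self):
        cfg = CohortSimConfig(
            group_sizes={"BRAF": 2, "NRAS": 0, "WT": 0, "GNAQ/GNA11": 0},
            n_events=150, seed=2, mhc1_loss_fraction=1.0)
        truth = generate_cohort(cfg).truth
        assert (truth["HLA-ABC_true_rmfi_pre"] < 1.1).all()
        assert (truth["HLA-ABC_true_fold"] < 1.5).all()

    def test_determinism(self):
        cfg = CohortSimConfig(
            group_sizes={"BRAF": 1, "NRAS": 1, "WT": 0, "GNAQ/GNA11": 0},
            n_events=150, seed=9)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.truth.equals(b.truth)
        key = next(iter(a.tubes))
        assert a.tubes[key].data.equals(b.tubes[key].data)
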