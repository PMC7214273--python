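import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meth3dlink import dmc_calling as dmc
from meth3dlink.exceptions import InputError
from meth3dlink.io_formats import BetaMatrix, SampleMeta
from meth3dlink.synthetic_data import SimConfig, generate_dataset

from conftest import make_beta_matrix


def welch_oracle(a, b):
    """Textbook Welch t: statistic, Welch-Satterthwaite df, two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestDeltaBeta:
    def test_endpoint_arithmetic(self):
        bm = make_beta_matrix({"cgA": {0: [0.90, 0.90], 168: [0.20, 0.20]}})
        assert dmc.delta_beta(bm, "cgA", 0, 168) == pytest.approx(-0.70)

    def test_identical_values_give_zero(self):
        bm = make_beta_matrix({"cgA": {0: [0.4, 0.4], 168: [0.4, 0.4]}})
        assert dmc.delta_beta(bm, "cgA", 0, 168) == 0.0

    def test_missing_timepoint_is_input_error(self):
        bm = make_beta_matrix({"cgA": {0: [0.4], 168: [0.4]}})
        with pytest.raises(InputError):
            dmc.delta_beta(bm, "cgA", 0, 72)


class TestTestProbe:
    def test_no_signal_convention_p_is_one(self):
        bm = make_beta_matrix({"cgA": {0: [0.5, 0.5, 0.5], 168: [0.5, 0.5, 0.5]}})
        assert dmc.test_probe(bm, "cgA") == 1.0

    def test_clear_separation_is_significant(self):
        bm = make_beta_matrix(
            {"cgA": {0: [0.8, 0.9, 0.85], 168: [0.1, 0.15, 0.12]}}
        )
        p = dmc.test_probe(bm, "cgA")
        assert p < 0.01
        assert p == pytest.approx(
            welch_oracle([0.8, 0.9, 0.85], [0.1, 0.15, 0.12]), abs=1e-10
        )

    def test_anova_identical_group_means_p_is_one(self):
        bm = make_beta_matrix(
            {"cgA": {t: [0.3, 0.3] for t in (0, 3, 12, 24, 48, 72, 168)}}
        )
        assert dmc.test_probe(bm, "cgA", method="anova_f") == 1.0

    def test_anova_detects_shift(self):
        rows = {t: [0.8 + 0.001 * i for i in range(3)] for t in (0, 3, 12)}
        rows.update({t: [0.1 + 0.001 * i for i in range(3)] for t in (24, 48, 72, 168)})
        bm = make_beta_matrix({"cgA": rows})
        assert dmc.test_probe(bm, "cgA", method="anova_f") < 1e-6

    def test_insufficient_replicates_is_input_error(self):
        bm = make_beta_matrix({"cgA": {0: [0.5], 168: [0.4]}})
        with pytest.raises(InputError):
            dmc.test_probe(bm, "cgA")

    def test_welch_matches_textbook_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            na, nb = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            a = rng.uniform(0.05, 0.95, na)
            b = rng.uniform(0.05, 0.95, nb)
            bm = make_beta_matrix({"cgA": {0: list(a), 168: list(b)}})
            assert dmc.test_probe(bm, "cgA") == pytest.approx(
                welch_oracle(a, b), abs=1e-10
            )


class TestCallDmcs:
    def _planted_matrix(self, n_null=100, n_planted=10):
        rows = {}
        for i in range(n_planted):
            rows[f"hypo{i:02d}"] = {
                0: [0.85, 0.851, 0.849],
                168: [0.15, 0.151, 0.149],
            }
        for i in range(n_null):
            v = 0.3 + 0.004 * i
            rows[f"null{i:03d}"] = {0: [v, v + 0.001, v - 0.001],
                                    168: [v, v + 0.001, v - 0.001]}
        return make_beta_matrix(rows)

    def test_noiseless_planted_recovery(self):
        records = dmc.call_dmcs(self._planted_matrix())
        passing = [r for r in records if r.passes]
        assert {r.probe_id for r in passing} == {f"hypo{i:02d}" for i in range(10)}
        assert all(r.direction == "hypo" for r in passing)

    def test_unattainable_delta_threshold_gives_zero_passes(self):
        records = dmc.call_dmcs(self._planted_matrix(), delta_threshold=1.01)
        assert not any(r.passes for r in records)

    def test_direction_labels_match_planted_at_zero_noise(self):
        ds = generate_dataset(
            SimConfig(n_probes=200, n_planted_hypo=20, n_planted_hyper=5,
                      beta_noise_sd=0.0, expr_noise_sd=0.0, n_genes=50,
                      n_interactions=30, n_local_activation=4,
                      n_local_repression=1, n_distal_enhancer_genes=3,
                      n_distal_silencer_genes=2, n_dual_probes=1, seed=4)
        )
        records = {r.probe_id: r for r in dmc.call_dmcs(ds.beta)}
        for pid, direction in ds.truth.dmc_direction.items():
            assert records[pid].passes
            assert records[pid].direction == direction

    def test_delta_exactly_at_threshold_passes(self):
        # |delta beta| = 0.66 exactly must pass the inclusive magnitude filter
        rows = {"cgA": {0: [0.86, 0.861, 0.859], 168: [0.20, 0.201, 0.199]}}
        records = dmc.call_dmcs(make_beta_matrix(rows))
        (rec,) = records
        assert rec.delta_beta == pytest.approx(-0.66)
        assert rec.passes

    def test_output_invariant_to_row_and_column_order(self):
        bm = self._planted_matrix(n_null=20, n_planted=5)
        rng = np.random.default_rng(0)
        shuffled_rows = bm.values.sample(frac=1, random_state=1)
        shuffled = BetaMatrix(
            shuffled_rows[list(rng.permutation(bm.values.columns))], bm.samples
        )
        a = {r.probe_id: r for r in dmc.call_dmcs(bm)}
        b = {r.probe_id: r for r in dmc.call_dmcs(shuffled)}
        assert set(a) == set(b)
        for pid in a:
            assert a[pid].p_value == pytest.approx(b[pid].p_value, abs=1e-12)
            assert a[pid].passes == b[pid].passes

    @pytest.mark.parametrize("adjust", ["none", "bh"])
    def test_pass_sets_monotone_in_thresholds(self, adjust):
        bm = self._planted_matrix(n_null=50, n_planted=5)
        thresholds = [0.001, 0.01, 0.05, 0.2]
        prev: set[str] = set()
        for pt in thresholds:
            cur = {
                r.probe_id
                for r in dmc.call_dmcs(bm, p_threshold=pt, adjust=adjust)
                if r.passes
            }
            assert prev <= cur
            prev = cur
        prev = None
        for dt in [0.9, 0.66, 0.3, 0.0]:
            cur = {
                r.probe_id
                for r in dmc.call_dmcs(bm, delta_threshold=dt, adjust=adjust)
                if r.passes
            }
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_empty_matrix_is_input_error(self):
        bm = make_beta_matrix({"cgA": {0: [0.5, 0.5], 168: [0.5, 0.5]}})
        empty = BetaMatrix(bm.values.iloc[:0], bm.samples)
        with pytest.raises(InputError):
            dmc.call_dmcs(empty)


class TestControlConcordance:
    def _with_controls(self, beta168, pos, neg):
        samples = [
            SampleMeta("t000_r1", 0, 1, "transdiff"),
            SampleMeta("t000_r2", 0, 2, "transdiff"),
            SampleMeta("t168_r1", 168, 1, "transdiff"),
            SampleMeta("t168_r2", 168, 2, "transdiff"),
            SampleMeta("neg_r1", None, 1, "negative_control"),
            SampleMeta("pos_r1", None, 1, "positive_control"),
        ]
        values = pd.DataFrame(
            {
                "t000_r1": [0.9], "t000_r2": [0.9],
                "t168_r1": [beta168], "t168_r2": [beta168],
                "neg_r1": [neg], "pos_r1": [pos],
            },
            index=pd.Index(["cgA"], name="probe_id"),
        )
        bm = BetaMatrix(values, samples)
        rec = dmc.DMCRecord("cgA", 0.9, beta168, beta168 - 0.9, 1e-6, 1e-6,
                            "hypo", True)
        return bm, [rec]

    def test_exact_match_to_positive_control(self):
        bm, recs = self._with_controls(beta168=0.1, pos=0.1, neg=0.9)
        (c,) = dmc.control_concordance(bm, recs)
        assert c.macrophage_like and c.dist_to_positive == 0.0

    def test_match_to_negative_control_is_not_macrophage_like(self):
        bm, recs = self._with_controls(beta168=0.9, pos=0.1, neg=0.9)
        (c,) = dmc.control_concordance(bm, recs)
        assert not c.macrophage_like

    def test_missing_control_is_input_error(self, default_dataset):
        ds = default_dataset
        cols = ds.beta.columns_for("transdiff")
        no_controls = BetaMatrix(
            ds.beta.values[cols],
            [s for s in ds.beta.samples if s.condition == "transdiff"],
        )
        with pytest.raises(InputError):
            dmc.control_concordance(no_controls, [])

    def test_planted_dmcs_are_macrophage_like_on_default_study(self, default_dataset):
        ds = default_dataset
        records = dmc.call_dmcs(ds.beta)
        conc = dmc.control_concordance(ds.beta, records)
        assert dmc.macrophage_like_fraction(conc) >= 0.95
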