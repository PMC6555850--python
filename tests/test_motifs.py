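"""PWM affinity scanning and lognormal-background enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regscore import motifs as mo

RC = str.maketrans("ACGTN", "TGCAN")


def random_pwm(rng, length=8, name="tf"):
    mat = rng.dirichlet(np.ones(4), size=length).T
    return mo.PWM(tf_name=name, matrix=mat, pseudocount=0.0)


def naive_affinity(seq: str, pwm: mo.PWM) -> float:
    """Per-window double loop over both strands; the brute-force oracle."""
    def window_lr(window: str, matrix) -> float:
        lr = 1.0
        for j, base in enumerate(window):
            if base == "N":
                continue
            i = "ACGT".index(base)
            lr *= matrix[i, j] / pwm.background_freqs[i]
        return lr

    L = pwm.length
    rc = seq.translate(RC)[::-1]
    scores = []
    for s in (seq, rc):
        for i in range(len(s) - L + 1):
            scores.append(window_lr(s[i : i + L], pwm.matrix))
    return float(np.mean(scores))


class TestPwmAffinity:
    def test_background_pwm_scores_exactly_one(self):
        pwm = mo.PWM("flat", np.full((4, 6), 0.25), pseudocount=0.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=50))
            assert mo.pwm_affinity(seq, pwm) == pytest.approx(1.0, abs=1e-12)

    def test_consensus_sequence_hand_evaluated(self):
        # motif-length sequence: one window per strand, affinity is the
        # mean of the two window likelihood ratios
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, length=6)
        seq = pwm.consensus
        fwd = np.prod([pwm.matrix["ACGT".index(b), j] / 0.25
                       for j, b in enumerate(seq)])
        rc = seq.translate(RC)[::-1]
        rev = np.prod([pwm.matrix["ACGT".index(b), j] / 0.25
                       for j, b in enumerate(rc)])
        assert mo.pwm_affinity(seq, pwm) == pytest.approx((fwd + rev) / 2, rel=1e-12)

    def test_n_bases_are_neutral(self):
        rng = np.random.default_rng(4)
        pwm = random_pwm(rng, length=5)
        assert mo.pwm_affinity("N" * 20, pwm) == pytest.approx(1.0, abs=1e-12)

    def test_too_short_sequence_errors(self):
        pwm = random_pwm(np.random.default_rng(1), length=8)
        with pytest.raises(ValueError, match="shorter"):
            mo.pwm_affinity("ACGT", pwm)

    @pytest.mark.parametrize("seed", range(3))
    def test_against_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, length=int(rng.integers(5, 12)))
        for _ in range(15):
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04],
                                     size=200))
            assert mo.pwm_affinity(seq, pwm) == pytest.approx(
                naive_affinity(seq, pwm), rel=1e-12
            )

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=12, max_size=60),
           st.integers(0, 10_000))
    def test_reverse_complement_invariance(self, seq, pwm_seed):
        pwm = random_pwm(np.random.default_rng(pwm_seed), length=8)
        rc = seq.translate(RC)[::-1]
        assert mo.pwm_affinity(seq, pwm) == pytest.approx(
            mo.pwm_affinity(rc, pwm), rel=1e-9
        )


class TestBackground:
    def test_600bp_region_gives_three_chunks(self):
        assert len(mo.tile_chunks(["A" * 600], 200)) == 3
        assert len(mo.tile_chunks(["A" * 799], 200)) == 3  # partial dropped

    def test_too_few_chunks_errors_with_count(self):
        pwm = random_pwm(np.random.default_rng(0))
        with pytest.raises(ValueError, match="3 chunks"):
            mo.fit_background(["A" * 600], pwm)

    def test_constant_chunks_error(self):
        pwm = random_pwm(np.random.default_rng(0))
        with pytest.raises(ValueError, match="sigma = 0"):
            mo.fit_background(["ACGTACGTAC" * 20] * 150, pwm)

    def test_recovers_normal_parameters(self):
        rng = np.random.default_rng(21)
        mu, sigma = mo.fit_lognormal(rng.normal(-2.0, 0.5, size=10_000))
        assert mu == pytest.approx(-2.0, abs=0.02)
        assert sigma == pytest.approx(0.5, abs=0.02)

    def test_fit_background_matches_direct_estimate(self):
        rng = np.random.default_rng(6)
        pwm = random_pwm(rng)
        regions = ["".join(rng.choice(list("ACGT"), size=450)) for _ in range(60)]
        bg = mo.fit_background(regions, pwm)
        logs = [np.log(mo.pwm_affinity(c, pwm)) for c in mo.tile_chunks(regions)]
        assert bg.n_chunks == 120
        assert bg.mu == pytest.approx(np.mean(logs), rel=1e-12)
        assert bg.sigma == pytest.approx(np.std(logs, ddof=1), rel=1e-12)


class TestEnrich:
    def _pool_and_bg(self, seed=9, n=300, pwm_len=8):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng, length=pwm_len)
        pool = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(n)]
        return rng, pwm, pool, mo.fit_background(pool, pwm)

    def test_foreground_at_mu_gives_half(self):
        rng, pwm, pool, bg = self._pool_and_bg()
        seq = pool[0]
        bg.mu = float(np.log(mo.pwm_affinity(seq, pwm)))
        group, per_region = mo.enrich([seq], pwm, bg)
        assert group.p_value == pytest.approx(0.5, abs=1e-12)
        assert per_region[0].p_value == pytest.approx(0.5, abs=1e-12)

    def test_empty_foreground_errors(self):
        _, pwm, _, bg = self._pool_and_bg()
        with pytest.raises(ValueError, match="empty"):
            mo.enrich([], pwm, bg)

    def test_group_p_monotone_in_affinity(self):
        rng, pwm, pool, bg = self._pool_and_bg()
        seqs = sorted(pool[:20], key=lambda s: mo.pwm_affinity(s, pwm))
        p_low = mo.enrich(seqs[:5], pwm, bg)[0].p_value
        p_high = mo.enrich(seqs[-5:], pwm, bg)[0].p_value
        assert p_high < p_low

    def test_null_calibration_small(self):
        from scipy import stats

        rng, pwm, pool, bg = self._pool_and_bg(seed=17, n=400)
        pvals = []
        for _ in range(100):
            idx = rng.choice(len(pool), size=10, replace=True)
            group, _ = mo.enrich([pool[i] for i in idx], pwm, bg)
            pvals.append(group.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_consensus_is_detected(self):
        rng, pwm, pool, bg = self._pool_and_bg(seed=23)
        fg = []
        for i in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            if i < 6:  # plant in 60% of regions
                pos = int(rng.integers(0, 200 - pwm.length))
                seq = seq[:pos] + pwm.consensus + seq[pos + pwm.length:]
            fg.append(seq)
        group, _ = mo.enrich(fg, pwm, bg)
        assert group.p_value < 1e-4


class TestCandidateTfs:
    def _results(self):
        return [
            mo.MotifEnrichmentResult("TF_A", "grp", 1.0, 1e-5, 10),
            mo.MotifEnrichmentResult("TF_B", "grp", 1.0, 5e-5, 10),
            mo.MotifEnrichmentResult("TF_C", "grp", 1.0, 0.2, 10),
            mo.MotifEnrichmentResult("TF_D", "grp", 1.0, 1e-6, 10),
        ]

    def _expr(self, fpkms):
        import pandas as pd

        return pd.DataFrame({"t.rep1": list(fpkms.values())},
                            index=list(fpkms.keys()))

    def test_expression_clause_excludes_low_fpkm(self):
        expr = self._expr({"TF_A": 3.0, "TF_B": 0.5, "TF_C": 3.0, "TF_D": 3.0})
        out = mo.candidate_tfs(self._results(), expr, p_max=1e-4)
        assert list(out["tf"]) == ["TF_D", "TF_A"]  # sorted by p, B fails FPKM

    def test_missing_tf_dropped_with_warning(self, caplog):
        expr = self._expr({"TF_A": 3.0})
        with caplog.at_level("WARNING"):
            out = mo.candidate_tfs(self._results(), expr, p_max=1e-4)
        assert list(out["tf"]) == ["TF_A"]
        assert "dropped" in caplog.text

    def test_against_row_filter_oracle(self):
        rng = np.random.default_rng(11)
        names = [f"TF{i:02d}" for i in range(40)]
        results = [mo.MotifEnrichmentResult(n, "grp", 1.0,
                                            float(10 ** -rng.uniform(0, 6)), 5)
                   for n in names]
        fpkm = {n: float(rng.lognormal(0, 1)) for n in names}
        out = mo.candidate_tfs(results, self._expr(fpkm), p_max=1e-2)
        expected = sorted(
            [r.tf_name for r in results
             if r.p_value < 1e-2 and fpkm[r.tf_name] > 1.0],
            key=lambda n: (next(r.p_value for r in results if r.tf_name == n), n),
        )
        assert list(out["tf"]) == expected


class TestJasparIO:
    def test_round_trip_preserves_consensus_and_shape(self, tmp_path):
        rng = np.random.default_rng(2)
        pwms = [random_pwm(rng, length=int(rng.integers(6, 12)), name=f"TF{i}")
                for i in range(4)]
        path = tmp_path / "m.jaspar"
        mo.write_jaspar(pwms, path)
        back = mo.read_jaspar(path)
        assert [p.tf_name for p in back] == [p.tf_name for p in pwms]
        for a, b in zip(pwms, back):
            assert a.length == b.length
            assert a.consensus == b.consensus
            assert np.allclose(a.matrix, b.matrix, atol=5e-3)
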