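"""Tests for the iterative template-matching latency estimator."""

import numpy as np
import pandas as pd
import pytest

from erpoverlap import pipeline as pipe
from erpoverlap import preprocess as pre
from erpoverlap import stats as stats_mod
from erpoverlap import synthetic_data as synth
from erpoverlap import woody
from erpoverlap.containers import EpochSet, round_half_away

from conftest import make_bump_epochs, make_trial_table


def brute_force_pass(x, template, t0, sfreq, window, halfwidth, normalized):
    """Independent oracle: one matching pass by plain loops.

    Scores every candidate center with an explicitly coded correlation and
    finds the largest positive local maximum by scanning for derivative sign
    changes.
    """
    n_trials, n = x.shape
    half = int(round_half_away(halfwidth * sfreq))
    c0 = max(int(round_half_away((window[0] - t0) * sfreq)), 0)
    c1 = min(int(round_half_away((window[1] - t0) * sfreq)), n - 1)
    centers = list(range(c0, c1 + 1))
    out_idx, found = [], []
    for i in range(n_trials):
        scores = []
        for c in centers:
            lo, hi = max(0, c - half), min(n, c + half + 1)
            seg = x[i, lo:hi]
            tseg = template[lo - (c - half): lo - (c - half) + hi - lo]
            if normalized:
                s = np.corrcoef(seg, tseg)[0, 1]
                if not np.isfinite(s):
                    s = 0.0
            else:
                s = float(seg @ tseg) * (2 * half + 1) / len(tseg)
            scores.append(s)
        best_val, best_pos = -np.inf, None
        for j in range(1, len(scores) - 1):
            if (scores[j] - scores[j - 1] > 0
                    and scores[j + 1] - scores[j] <= 0
                    and scores[j] > 0 and scores[j] > best_val):
                best_val, best_pos = scores[j], j
        out_idx.append(centers[best_pos] if best_pos is not None else None)
        found.append(best_pos is not None)
    return out_idx, found


class TestNoiselessRecovery:
    def test_within_one_sample_and_oracle_agreement(self):
        """Noiseless bumps at known grid latencies: 4 iterations recover each
        latency to within one sample, and the final pass agrees exactly with
        the exhaustive-shift brute-force oracle."""
        rng = np.random.default_rng(3)
        sfreq = 256.0
        true = np.round(rng.uniform(0.42, 0.78, 60) * sfreq) / sfreq
        ep = make_bump_epochs(true)
        init = true + rng.normal(0, 0.03, len(true))
        cfg = woody.WoodyConfig(prefilter_band=None)
        lt = woody.estimate_latencies(ep, init, cfg)
        err_samples = np.abs(lt.latencies - true) * sfreq
        assert err_samples.max() <= 1.0 + 1e-9
        # oracle agreement on the final template
        oracle_idx, oracle_found = brute_force_pass(
            ep.data[:, 0, :], lt.template, ep.t0, sfreq,
            cfg.search_window, cfg.template_halfwidth, cfg.normalized)
        est_idx = round_half_away((lt.latencies - ep.t0) * sfreq)
        for got, want, ok in zip(est_idx, oracle_idx, oracle_found):
            assert ok and got == want

    def test_consistent_offset_is_preserved(self):
        """The iteration is translation-invariant: a uniform offset in the
        initial estimates survives (latency is defined relative to the
        seeding, a property of the method itself)."""
        rng = np.random.default_rng(4)
        sfreq = 256.0
        true = np.round(rng.uniform(0.45, 0.70, 50) * sfreq) / sfreq
        ep = make_bump_epochs(true)
        offset = 13 / sfreq
        lt = woody.estimate_latencies(ep, true + offset,
                                      woody.WoodyConfig(prefilter_band=None))
        kept = ~lt.table["flagged"].to_numpy()
        err = (lt.latencies - (true + offset))[kept] * sfreq
        assert np.abs(err).max() <= 1.0 + 1e-9


class TestScoreDefinition:
    def test_impulse_template_scores_equal_signal(self):
        """With a single-sample impulse template and the raw dot-product
        score, the score sequence is the windowed signal itself, so the
        estimate is the signal's largest positive interior peak."""
        rng = np.random.default_rng(5)
        sfreq = 256.0
        x = rng.standard_normal((12, 410))
        ep = EpochSet(data=x[:, None, :], t0=-0.1015625, sfreq=sfreq,
                      lock="target", channel_names=("Pz",),
                      metadata=pd.DataFrame({"trial_id": np.arange(12)}))
        cfg = woody.WoodyConfig(prefilter_band=None, normalized=False,
                                n_iterations=1)
        half = int(round_half_away(cfg.template_halfwidth * sfreq))
        template = np.zeros(2 * half + 1)
        template[half] = 1.0
        lt = woody.reuse_template(template, ep, cfg)
        # oracle: scan the raw signal inside the window for its largest
        # positive interior local maximum
        c0 = int(round_half_away((0.35 - ep.t0) * sfreq))
        c1 = int(round_half_away((0.90 - ep.t0) * sfreq))
        for i in range(12):
            seg = x[i, c0:c1 + 1]
            best, pos = -np.inf, None
            for j in range(1, len(seg) - 1):
                if (seg[j] > seg[j - 1] and seg[j + 1] <= seg[j]
                        and seg[j] > 0 and seg[j] > best):
                    best, pos = seg[j], j
            got = int(round_half_away((lt.latencies[i] - ep.t0) * sfreq))
            assert got == c0 + pos

    def test_amplitude_invariance(self):
        """Scaling all epochs by c > 0 leaves the estimates unchanged."""
        rng = np.random.default_rng(6)
        true = np.round(rng.uniform(0.45, 0.75, 40) * 256) / 256
        noise = 0.5 * rng.standard_normal((40, 410))
        ep = make_bump_epochs(true, noise=noise)
        init = true + rng.normal(0, 0.03, 40)
        for normalized in (True, False):
            cfg = woody.WoodyConfig(prefilter_band=None, normalized=normalized)
            base = woody.estimate_latencies(ep, init, cfg)
            scaled = woody.estimate_latencies(
                ep.copy_with(data=ep.data * 3.7), init, cfg)
            assert np.array_equal(base.latencies, scaled.latencies)

    def test_shift_equivariance(self):
        """Delaying every epoch by k samples (with inits and search window
        shifted accordingly) shifts all estimates by exactly k samples."""
        rng = np.random.default_rng(7)
        sfreq = 256.0
        true = np.round(rng.uniform(0.45, 0.65, 30) * sfreq) / sfreq
        noise = 0.3 * rng.standard_normal((30, 410))
        ep = make_bump_epochs(true, noise=noise)
        init = true + rng.normal(0, 0.02, 30)
        k = 12
        shifted = ep.copy_with(data=np.roll(ep.data, k, axis=2))
        cfg = woody.WoodyConfig(prefilter_band=None,
                                search_window=(0.40, 0.75))
        cfg_k = woody.WoodyConfig(prefilter_band=None,
                                  search_window=(0.40 + k / sfreq,
                                                 0.75 + k / sfreq))
        a = woody.estimate_latencies(ep, init, cfg)
        b = woody.estimate_latencies(shifted, init + k / sfreq, cfg_k)
        assert np.allclose(b.latencies - a.latencies, k / sfreq)


class TestIterationBehaviour:
    def test_convergence_bookkeeping_nonincreasing(self):
        """On noiseless single-component data the mean absolute estimate
        change per iteration is non-increasing."""
        rng = np.random.default_rng(8)
        true = np.round(rng.uniform(0.45, 0.75, 80) * 256) / 256
        ep = make_bump_epochs(true)
        init = true + rng.normal(0, 0.04, 80)
        lt = woody.estimate_latencies(ep, init,
                                      woody.WoodyConfig(prefilter_band=None))
        changes = lt.iteration_mean_abs_change
        assert all(b <= a + 1e-12 for a, b in zip(changes, changes[1:]))

    def test_zero_signal_flags_all_and_keeps_inits(self):
        ep = make_bump_epochs(np.full(10, 0.5), amplitude=0.0)
        init = np.linspace(0.45, 0.75, 10)
        with pytest.warns(UserWarning, match="no positive score peak"):
            lt = woody.estimate_latencies(
                ep, init, woody.WoodyConfig(prefilter_band=None))
        assert lt.table["flagged"].all()
        init_idx = round_half_away((init - ep.t0) * ep.sfreq)
        got_idx = round_half_away((lt.latencies - ep.t0) * ep.sfreq)
        assert np.array_equal(got_idx, init_idx)
        assert lt.table["score"].isna().all()

    def test_init_count_mismatch_raises(self):
        ep = make_bump_epochs(np.full(5, 0.5))
        with pytest.raises(ValueError, match="one initial latency"):
            woody.estimate_latencies(ep, np.zeros(4))

    def test_empty_search_window_raises(self):
        ep = make_bump_epochs(np.full(5, 0.5))
        with pytest.raises(ValueError, match="search window"):
            woody.estimate_latencies(
                ep, np.full(5, 0.5),
                woody.WoodyConfig(search_window=(2.0, 3.0)))


class TestTemplateReuse:
    def test_self_consistency(self):
        """Re-using the final template on the epochs that built it reproduces
        the source estimates."""
        rng = np.random.default_rng(9)
        true = np.round(rng.uniform(0.45, 0.75, 60) * 256) / 256
        noise = 0.4 * rng.standard_normal((60, 410))
        ep = make_bump_epochs(true, noise=noise)
        cfg = woody.WoodyConfig(prefilter_band=None)
        lt = woody.estimate_latencies(ep, true + rng.normal(0, 0.03, 60), cfg)
        lt2 = woody.reuse_template(lt.template, ep, cfg)
        assert np.array_equal(lt.latencies, lt2.latencies)

    def test_rate_mismatch_raises(self):
        ep = make_bump_epochs(np.full(5, 0.5))
        with pytest.raises(ValueError, match="rate"):
            woody.reuse_template(np.zeros(257), ep,
                                 template_sfreq=128.0)

    def test_template_length_mismatch_raises(self):
        ep = make_bump_epochs(np.full(5, 0.5))
        with pytest.raises(ValueError, match="length"):
            woody.reuse_template(np.zeros(100), ep,
                                 woody.WoodyConfig(prefilter_band=None))

    def test_delayed_without_p3_uncorrelated_with_as(self):
        """Template re-use on a delayed condition with no injected P3 and a
        flat (non-graded) N400 yields latencies unrelated to association
        strength (permutation test).

        With the default AS-graded N400 the matcher's score landscape shifts
        systematically with N400 amplitude, so latency picks up a genuine AS
        signature even without any P3; the AS-flat world is the true null for
        the estimator.
        """
        pairs = synth.generate_stimulus_list(n_total=200, n_zero=25, n_top=25,
                                             seed=21)
        profiles = synth.default_profiles(1, "delayed", seed=21)
        trials = synth.simulate_behavior(pairs, profiles, "delayed", seed=21)
        cfg = synth.SimulationConfig(
            n_subjects=1, n_pairs=200, condition="delayed",
            channel_names=("Pz", "Cz", "Oz"),
            component_specs=synth.default_components(
                "delayed", n400_base=-2.5, n400_logas_slope=0.0))
        rec, _ = synth.simulate_eeg(trials, cfg, seed=21)
        ep = pre.run_chain(rec, trials)

        # template trained on a speeded run of the same subject
        sp_trials = synth.simulate_behavior(
            pairs, synth.default_profiles(1, "speeded", seed=21), "speeded",
            seed=22, trial_id_start=10_000)
        sp_cfg = synth.SimulationConfig(
            n_subjects=1, n_pairs=200, condition="speeded",
            channel_names=("Pz", "Cz", "Oz"))
        sp_rec, _ = synth.simulate_eeg(sp_trials, sp_cfg, seed=22)
        sp_ep = pre.run_chain(sp_rec, sp_trials)
        wc = woody.WoodyConfig()
        sp_lt = woody.estimate_latencies(
            sp_ep, sp_ep.metadata["rt_s"].to_numpy(), wc)

        lt = woody.reuse_template(sp_lt.template, ep, wc,
                                  template_sfreq=sp_lt.sfreq)
        merged = ep.metadata.assign(latency=lt.latencies)
        merged = merged[merged["as_score"] > 0]
        la = np.log(merged["as_score"].to_numpy(dtype=float))
        lat = merged["latency"].to_numpy()
        r_obs = np.corrcoef(lat, la)[0, 1]
        rng = np.random.default_rng(0)
        null = np.array([np.corrcoef(rng.permutation(lat), la)[0, 1]
                         for _ in range(400)])
        assert (np.abs(null) >= abs(r_obs)).mean() > 0.05

    def test_weak_covert_p3_recovered(self):
        """A weak delayed-condition P3 whose latency tracks each pair's
        speeded-condition mean RT yields a positive, significant regression
        weight of estimated latency on that mean RT."""
        pairs = synth.generate_stimulus_list(n_total=300, n_zero=38, n_top=38,
                                             seed=23)
        profiles = synth.default_profiles(3, "speeded", seed=23)
        sp_trials = synth.simulate_behavior(pairs, profiles, "speeded",
                                            seed=23)
        mean_rt = sp_trials.groupby("pair_id")["rt_s"].mean()
        rows = []
        wc = woody.WoodyConfig()
        for prof in profiles:
            # covert decision: P3 at the pair's typical speeded RT although
            # the overt response is cued much later
            covert = make_trial_table(
                len(pairs), rt=mean_rt.loc[[p.pair_id for p in pairs]].to_numpy(),
                subject_id=prof.subject_id,
                as_score=[p.as_score for p in pairs],
                trial_id_start=100_000 * (prof.subject_id + 1))
            cfg = synth.SimulationConfig(
                n_subjects=1, n_pairs=len(pairs), condition="speeded",
                channel_names=("Pz", "Cz", "Oz"))
            rec, _ = synth.simulate_eeg(covert, cfg,
                                        seed=31 + prof.subject_id)
            ep = pre.run_chain(rec, covert)
            sp_sub = sp_trials[sp_trials["subject_id"] == prof.subject_id]
            # speeded template for this subject
            sp_cfg = synth.SimulationConfig(
                n_subjects=1, n_pairs=len(pairs), condition="speeded",
                channel_names=("Pz", "Cz", "Oz"))
            sp_rec, _ = synth.simulate_eeg(sp_sub, sp_cfg,
                                           seed=41 + prof.subject_id)
            sp_ep = pre.run_chain(sp_rec, sp_trials)
            sp_lt = woody.estimate_latencies(
                sp_ep, sp_ep.metadata["rt_s"].to_numpy(), wc)
            lt = woody.reuse_template(sp_lt.template, ep, wc)
            df = ep.metadata.assign(latency=lt.latencies)
            df["mean_speeded_rt"] = mean_rt.loc[df["pair_id"]].to_numpy()
            rows.append(df)
        table = pd.concat(rows, ignore_index=True)
        fit = stats_mod.fit_lme(table, stats_mod.LmeSpec(
            "latency", "mean_speeded_rt"))
        assert fit.w > 0
        assert fit.p < 0.05


class TestPipelineDispatch:
    def test_template_reuse_runs_automatically_for_delayed(self):
        cfg = pipe.default_config(
            seed=3, n_subjects=1, n_pairs=48,
            simulation={"channel_names": ("Pz", "Cz", "Oz")},
        )
        sp_ep, _, _ = pipe.simulate_condition(cfg, "speeded")
        dl_ep, _, _ = pipe.simulate_condition(cfg, "delayed",
                                              trial_id_start=48)
        tables = pipe._estimate_latencies_by_subject(
            sp_ep, dl_ep, woody.WoodyConfig())
        conditions = {t.table["condition"].iloc[0] for t in tables}
        assert conditions == {"speeded", "delayed"}
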