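"""Schedule construction, counterbalancing, observer and behavioral ANOVA."""

import numpy as np
import pandas as pd
import pytest

from memdecode.study_design import (
    DEFAULT_P_CORRECT,
    STIMULUS_MAP,
    SubjectDesign,
    assign_groups,
    behavioral_table,
    build_encoding_schedule,
    build_retrieval_schedule,
    mixed_anova,
    simulate_observer,
)


class TestEncodingSchedule:
    def test_reference_design_counts(self):
        sched = build_encoding_schedule(60, 15, seed=0)
        assert sched.n_trials == 600  # 60 categories x (1+1+3+5) presentations
        assert sched.frame["image_id"].nunique() == 240  # 4 images per category
        reps = sched.frame.groupby("image_id").size()
        role = sched.frame.groupby("image_id")["stimulus_type"].first()
        expected = role.map({"1x": 1, "EO": 1, "3x": 3, "5x": 5})
        assert (reps == expected).all()

    def test_per_block_composition(self):
        sched = build_encoding_schedule(60, 15, seed=3)
        comp = sched.frame.groupby(["run", "stimulus_type"]).size().unstack()
        assert (comp["1x"] == 4).all()
        assert (comp["EO"] == 4).all()
        assert (comp["3x"] == 12).all()
        assert (comp["5x"] == 20).all()

    def test_scaled_design_and_determinism(self):
        a = build_encoding_schedule(2, 1, seed=0)
        b = build_encoding_schedule(2, 1, seed=0)
        comp = a.frame.groupby("stimulus_type").size()
        assert comp.to_dict() == {"1x": 2, "3x": 6, "5x": 10, "EO": 2}
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_indivisible_blocks_rejected(self):
        with pytest.raises(ValueError):
            build_encoding_schedule(60, 14, seed=0)

    def test_odd_categories_rejected(self):
        with pytest.raises(ValueError):
            build_encoding_schedule(59, 1, seed=0)


class TestRetrievalSchedule:
    def test_reference_counts(self):
        sched = build_retrieval_schedule(60, seed=0)
        assert sched.n_trials == 360
        assert (sched.frame["memory_status"] == "old").sum() == 180
        assert len(sched.runs) == 12
        per_cell = sched.frame.groupby(["memory_status", "evidence"]).size()
        assert (per_cell == 60).all()

    def test_per_run_composition_and_sides(self):
        sched = build_retrieval_schedule(60, seed=1)
        comp = sched.frame.groupby(["run", "stimulus_type"]).size()
        assert (comp == 5).all()
        sides = sched.frame.groupby("run")["target_side"].value_counts().unstack()
        assert (sides["left"] == 15).all() and (sides["right"] == 15).all()

    def test_stimulus_condition_map(self):
        sched = build_retrieval_schedule(20, seed=2)
        for stim, (status, ev) in STIMULUS_MAP.items():
            sub = sched.frame[sched.frame["stimulus_type"] == stim]
            assert (sub["memory_status"] == status).all()
            assert (sub["evidence"] == ev).all()

    def test_onsets_follow_trial_timing(self):
        sched = build_retrieval_schedule(20, seed=0)
        t = sched.timing
        for _, run in sched.frame.groupby("run"):
            gaps = np.diff(run["onset"].to_numpy())
            base = t.image_s + t.delay_s + t.go_s
            itis = (gaps - base) / t.tr_s
            assert np.allclose(itis, np.round(itis))
            assert set(np.round(itis).astype(int)) <= set(t.iti_trs)

    def test_determinism(self):
        a = build_retrieval_schedule(60, seed=5)
        b = build_retrieval_schedule(60, seed=5)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_total_image_requirement(self):
        """Encoding images plus distinct new retrieval items = 420."""
        enc = build_encoding_schedule(60, 15, seed=0)
        ret = build_retrieval_schedule(60, seed=0)
        new = ret.frame[ret.frame["memory_status"] == "new"]
        n_new_images = len(new.groupby(["stimulus_type", "category"]))
        assert enc.frame["image_id"].nunique() + n_new_images == 420


class TestGroups:
    def test_balanced_and_reversed(self):
        designs = assign_groups(24, seed=0)
        groups = [d.group for d in designs]
        assert groups.count("A1") == 12 and groups.count("A2") == 12
        a1 = next(d for d in designs if d.group == "A1")
        a2 = next(d for d in designs if d.group == "A2")
        assert a1.mapping["old"] == a2.mapping["new"]
        assert a1.mapping["new"] == a2.mapping["old"]
        for d in designs:
            assert d.mapping["old"] != d.mapping["new"]

    def test_two_subjects(self):
        designs = assign_groups(2, seed=9)
        assert {d.group for d in designs} == {"A1", "A2"}

    def test_odd_rejected(self):
        with pytest.raises(ValueError):
            assign_groups(7, seed=0)

    def test_cohort_counterbalance_decorrelates_choice_and_response(self):
        """Across groups the choice and response labels are independent;
        within a subject they are perfectly collinear."""
        designs = assign_groups(8, seed=1)
        sched = build_retrieval_schedule(20, seed=0)
        choice_sign, response_sign = [], []
        for d in designs:
            obs = simulate_observer(sched, d, seed=d.subject_id)
            c = np.where(obs.frame["choice"] == "old", 1, -1)
            r = np.where(obs.frame["response"] == "eye", 1, -1)
            assert abs(np.corrcoef(c, r)[0, 1]) == pytest.approx(1.0)
            choice_sign.append(c)
            response_sign.append(r)
        c = np.concatenate(choice_sign)
        r = np.concatenate(response_sign)
        # balanced groups cancel the per-subject +/-1 correlations
        assert abs(np.corrcoef(c, r)[0, 1]) < 0.15


class TestObserver:
    def test_perfect_observer(self):
        sched = build_retrieval_schedule(20, seed=0)
        d = SubjectDesign(0, "A1", {"old": "eye", "new": "hand"})
        obs = simulate_observer(sched, d, {k: 1.0 for k in DEFAULT_P_CORRECT}, seed=0)
        assert (obs.frame["choice"] == obs.frame["memory_status"]).all()
        assert obs.frame["correct"].all()
        assert (obs.frame["response"] == obs.frame["choice"].map(d.mapping)).all()

    def test_chance_observer_symmetry(self):
        sched = build_retrieval_schedule(60, seed=0)
        d = SubjectDesign(0, "A2", {"old": "hand", "new": "eye"})
        accs = []
        for s in range(30):
            obs = simulate_observer(sched, d, {k: 0.5 for k in DEFAULT_P_CORRECT}, seed=s)
            accs.append(obs.frame["correct"].mean())
        n = 30 * 360
        assert abs(np.mean(accs) - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_cell_accuracies_converge_to_table(self):
        """Monte-Carlo: empirical cell accuracies recover the generating
        table within 3 binomial standard errors at >= 10^4 trials."""
        designs = assign_groups(30, seed=0)
        scheds = {}
        for d in designs:
            sched = build_retrieval_schedule(60, seed=3)
            scheds[d.subject_id] = simulate_observer(sched, d, seed=100 + d.subject_id)
        table = behavioral_table(scheds, designs)
        n_per_cell = 60 * 30  # trials per cell x subjects
        for (status, ev), p in DEFAULT_P_CORRECT.items():
            cell = table[(table["memory_status"] == status) & (table["evidence"] == ev)]
            se = np.sqrt(p * (1 - p) / n_per_cell)
            assert abs(cell["accuracy"].mean() - p) < 3 * se

    def test_bad_probability_rejected(self):
        sched = build_retrieval_schedule(20, seed=0)
        d = SubjectDesign(0, "A1", {"old": "eye", "new": "hand"})
        with pytest.raises(ValueError):
            simulate_observer(sched, d, {k: 1.5 for k in DEFAULT_P_CORRECT}, seed=0)


def _projection_anova_oracle(table):
    """Sequential design-matrix projection for the balanced split-plot design.

    Builds indicator matrices term by term, orthogonalizes each against all
    preceding terms and takes the squared norm of the projection as the
    term's sum of squares.
    """
    subs = sorted(table["subject_id"].unique())
    y = []
    meta = []
    for _, row in table.iterrows():
        y.append(row["accuracy"])
        meta.append((row["subject_id"], row["group"], row["memory_status"], row["evidence"]))
    y = np.array(y)

    def indicators(keyfunc):
        keys = sorted({keyfunc(m) for m in meta})
        M = np.zeros((len(meta), len(keys)))
        for i, m in enumerate(meta):
            M[i, keys.index(keyfunc(m))] = 1.0
        return M

    terms = [
        ("intercept", np.ones((len(meta), 1))),
        ("group", indicators(lambda m: m[1])),
        ("subject", indicators(lambda m: m[0])),
        ("memory_status", indicators(lambda m: m[2])),
        ("memory_status:group", indicators(lambda m: (m[1], m[2]))),
        ("status_x_subject", indicators(lambda m: (m[0], m[2]))),
        ("evidence", indicators(lambda m: m[3])),
        ("evidence:group", indicators(lambda m: (m[1], m[3]))),
        ("evidence_x_subject", indicators(lambda m: (m[0], m[3]))),
        ("memory_status:evidence", indicators(lambda m: (m[2], m[3]))),
        ("memory_status:evidence:group", indicators(lambda m: (m[1], m[2], m[3]))),
    ]
    ss = {}
    basis = np.zeros((len(meta), 0))
    for name, M in terms:
        X = np.hstack([basis, M])
        Q, _ = np.linalg.qr(np.hstack([basis, M]))
        proj_new = Q[:, : np.linalg.matrix_rank(X)]
        fit_prev = basis @ np.linalg.lstsq(basis, y, rcond=None)[0] if basis.shape[1] else 0.0
        fit_new = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        ss[name] = float(np.sum((fit_new - fit_prev) ** 2))
        basis = X
    ss["residual"] = float(np.sum((y - basis @ np.linalg.lstsq(basis, y, rcond=None)[0]) ** 2))
    return ss


class TestMixedAnova:
    @staticmethod
    def _toy_table(seed=0, n_per_group=2, effects=None):
        rng = np.random.default_rng(seed)
        effects = effects or {}
        rows = []
        sid = 0
        for g in ("A1", "A2"):
            for _ in range(n_per_group):
                u = rng.normal(0, 0.05)
                for st in ("old", "new"):
                    for i, ev in enumerate(("low", "middle", "high")):
                        acc = (
                            0.6
                            + effects.get("evidence", 0.0) * (i - 1)
                            + effects.get("memory_status", 0.0) * (1 if st == "new" else -1)
                            + effects.get("group", 0.0) * (1 if g == "A1" else -1)
                            + u
                            + rng.normal(0, 0.03)
                        )
                        rows.append(
                            dict(subject_id=sid, group=g, memory_status=st, evidence=ev, accuracy=acc)
                        )
                sid += 1
        return pd.DataFrame(rows)

    def test_constant_cells_give_zero_f(self):
        table = self._toy_table(seed=0)
        table["accuracy"] = 0.7
        out = mixed_anova(table).set_index("effect")
        assert (out["F"] == 0).all()
        assert (out["p"] == 1).all()

    def test_pure_evidence_effect_detected(self):
        table = self._toy_table(seed=1, n_per_group=12, effects={"evidence": 0.12})
        out = mixed_anova(table).set_index("effect")
        assert out.loc["evidence", "p"] < 1e-6
        assert out.loc["group", "p"] > 0.05
        # degrees of freedom match the 24-subject design
        assert out.loc["evidence", "df1"] == 2 and out.loc["evidence", "df2"] == 44
        assert out.loc["memory_status", "df2"] == 22

    def test_matches_projection_oracle(self):
        table = self._toy_table(seed=2, n_per_group=2)  # 4-subject toy
        out = mixed_anova(table).set_index("effect")
        ss = _projection_anova_oracle(table)
        for effect in (
            "group", "memory_status", "memory_status:group", "evidence",
            "evidence:group", "memory_status:evidence", "memory_status:evidence:group",
        ):
            assert out.loc[effect, "ss"] == pytest.approx(ss[effect], abs=1e-10)
        # error strata: subjects-within-group and the residual stratum
        f_group = (ss["group"] / 1) / (ss["subject"] / 2)
        assert out.loc["group", "F"] == pytest.approx(f_group, rel=1e-10)

    def test_unbalanced_rejected(self):
        table = self._toy_table(seed=3)
        with pytest.raises(ValueError):
            mixed_anova(table.iloc[:-1])

    def test_posthoc_pairwise_holm(self):
        from memdecode.study_design import posthoc_pairwise

        table = self._toy_table(seed=4, n_per_group=6, effects={"evidence": 0.12})
        out = posthoc_pairwise(table, "evidence")
        assert len(out) == 3  # all level pairs
        assert (out["p_holm"] >= out["p"] - 1e-15).all()
        assert (out["p_holm"] <= 1.0).all()
        # a strong graded effect separates the extreme levels
        extreme = out[(out["level_a"] == "high") & (out["level_b"] == "low")]
        assert extreme["p_holm"].iloc[0] < 0.01
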