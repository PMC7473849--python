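"""Trial schedules, group counterbalancing, a simulated observer, and the
behavioral mixed ANOVA for the item-recognition decision task.

The experiment has two sessions. At encoding, images from ``n_categories``
scene categories (half indoor, half outdoor) are shown with graded
repetition: per category one image is shown once (``1x``), one is shown at
encoding only (``EO``), one three times (``3x``) and one five times
(``5x``). At retrieval, subjects judge items old/new and report the choice
with a saccade or a pointing movement after a fixed 8 s delay; the
choice→effector mapping is reversed between two counterbalanced groups
(``A1``, ``A2``) so that, across the cohort, memory choice and motor
response are decorrelated. Decision evidence is manipulated through the
six retrieval stimulus types: encoding repetitions for old items and lure
similarity for new items.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STIMULUS_MAP",
    "TrialTiming",
    "SubjectDesign",
    "TrialSchedule",
    "build_encoding_schedule",
    "build_retrieval_schedule",
    "assign_groups",
    "simulate_observer",
    "DEFAULT_P_CORRECT",
    "mixed_anova",
    "posthoc_pairwise",
]

#: Fixed mapping stimulus type -> (memory status, evidence level).
#: Old-item evidence grows with encoding repetitions; new-item evidence
#: shrinks with lure similarity (SPR lures are hardest, hence low evidence).
STIMULUS_MAP = {
    "1x": ("old", "low"),
    "3x": ("old", "middle"),
    "5x": ("old", "high"),
    "SPR": ("new", "low"),
    "SR": ("new", "middle"),
    "U": ("new", "high"),
}

EVIDENCE_LEVELS = ("low", "middle", "high")
MEMORY_STATUSES = ("old", "new")

#: Numeric coding used by the regional evidence-slope model.
EVIDENCE_CODE = {"low": -1.0, "middle": 0.0, "high": 1.0}


@dataclass(frozen=True)
class TrialTiming:
    """Retrieval trial timing in seconds; ITI drawn uniformly in TR units."""

    tr_s: float = 1.914
    image_s: float = 1.5
    delay_s: float = 8.0
    go_s: float = 1.0
    iti_trs: tuple[int, ...] = (2, 3, 4)
    lead_in_trs: int = 2
    tail_trs: int = 8

    @property
    def go_onset_offset_s(self) -> float:
        """Go-signal onset relative to image onset (image + delay)."""
        return self.image_s + self.delay_s


@dataclass(frozen=True)
class SubjectDesign:
    """One subject's group assignment and choice->effector mapping."""

    subject_id: int
    group: str  # "A1" or "A2"
    mapping: dict[str, str] = field(hash=False)

    def response_for(self, choice: str) -> str:
        return self.mapping[choice]


# A1 fixed as old->eye / new->hand; A2 is the exact reversal. Which group
# carries which mapping is arbitrary and is recorded in the cohort sidecar.
GROUP_MAPPINGS = {
    "A1": {"old": "eye", "new": "hand"},
    "A2": {"old": "hand", "new": "eye"},
}


@dataclass
class TrialSchedule:
    """Ordered trials of one session as a table.

    ``frame`` columns (retrieval): onset, duration, run, stimulus_type,
    memory_status, evidence, image_type, target_side and — once an observer
    has responded — choice, response, correct.
    """

    frame: pd.DataFrame
    session: str
    tr_s: float
    timing: TrialTiming | None = None

    @property
    def n_trials(self) -> int:
        return len(self.frame)

    def run_frames(self, run: int) -> int:
        """Number of MR frames needed to cover a run, with tail padding."""
        sub = self.frame[self.frame["run"] == run]
        t = self.timing if self.timing is not None else TrialTiming(tr_s=self.tr_s)
        end_s = sub["onset"].max() + t.image_s + t.delay_s + t.go_s
        return int(np.ceil(end_s / self.tr_s)) + t.tail_trs

    @property
    def runs(self) -> list[int]:
        return sorted(self.frame["run"].unique().tolist())


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

# Per-category presentation counts at encoding, by role.
_ENCODING_ROLES = {"1x": 1, "EO": 1, "3x": 3, "5x": 5}


def build_encoding_schedule(
    n_categories: int = 60, n_blocks: int = 15, seed: int = 0
) -> TrialSchedule:
    """Build the encoding-session schedule.

    Each category contributes four images (roles 1x, EO, 3x, 5x) presented
    1, 1, 3 and 5 times respectively, so ``10 * n_categories`` presentations
    are divided evenly over ``n_blocks`` blocks; the reference design is 60
    categories over 15 blocks (blocks of 4 1x + 4 EO + 12 3x + 20 5x).
    """
    if n_categories % 2:
        raise ValueError("n_categories must be even (half indoor, half outdoor)")
    per_block = {}
    for role, reps in _ENCODING_ROLES.items():
        total = n_categories * reps
        if total % n_blocks:
            raise ValueError(
                f"cannot divide {total} {role} presentations into {n_blocks} blocks"
            )
        per_block[role] = total // n_blocks

    rng = np.random.default_rng(seed)
    half = n_categories // 2
    image_type = {c: ("indoor" if c < half else "outdoor") for c in range(n_categories)}

    # Presentation tokens per role, shuffled then dealt into blocks so every
    # block has the exact stated composition.
    rows = []
    block_tokens: list[list[tuple[str, int]]] = [[] for _ in range(n_blocks)]
    for role, reps in _ENCODING_ROLES.items():
        tokens = [(role, c) for c in range(n_categories) for _ in range(reps)]
        rng.shuffle(tokens)
        k = per_block[role]
        for b in range(n_blocks):
            block_tokens[b].extend(tokens[b * k : (b + 1) * k])

    trial_s = 4.0  # warning + image + response window + fixation
    for b, tokens in enumerate(block_tokens):
        order = rng.permutation(len(tokens))
        for i, j in enumerate(order):
            role, cat = tokens[j]
            rows.append(
                {
                    "onset": i * trial_s,
                    "duration": 1.0,
                    "run": b,
                    "stimulus_type": role,
                    "category": cat,
                    "image_id": f"cat{cat:03d}_{role}",
                    "image_type": image_type[cat],
                }
            )
    return TrialSchedule(pd.DataFrame(rows), session="encoding", tr_s=TrialTiming().tr_s)


def build_retrieval_schedule(
    n_categories: int = 60, seed: int = 0, timing: TrialTiming | None = None
) -> TrialSchedule:
    """Build the retrieval-session schedule.

    Old items are the 1x/3x/5x encoding images (one per category); new
    items are unrelated (U), semantically related (SR) and
    semantic-plus-perceptual (SPR) lures, one per category. Runs hold 30
    trials, 5 per stimulus type; target side is balanced within run; the
    inter-trial interval is drawn uniformly from 2-4 MR frames.
    """
    if n_categories % 10:
        raise ValueError("n_categories must be a multiple of 10 (runs of 30 trials)")
    timing = timing or TrialTiming()
    n_runs = (6 * n_categories) // 30
    per_type_per_run = n_categories // n_runs  # = 5 in the reference design
    rng = np.random.default_rng(seed)

    half = n_categories // 2
    rows = []
    # One item per stimulus type per category; deal categories to runs.
    for stim in STIMULUS_MAP:
        cats = rng.permutation(n_categories)
        for r in range(n_runs):
            for c in cats[r * per_type_per_run : (r + 1) * per_type_per_run]:
                status, evidence = STIMULUS_MAP[stim]
                rows.append(
                    {
                        "run": r,
                        "stimulus_type": stim,
                        "category": int(c),
                        "memory_status": status,
                        "evidence": evidence,
                        "image_type": "indoor" if c < half else "outdoor",
                    }
                )
    frame = pd.DataFrame(rows)

    out = []
    for r in range(n_runs):
        sub = frame[frame["run"] == r].sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
        n = len(sub)
        sides = np.array(["left", "right"])[
            rng.permutation(np.arange(n) % 2)
        ]
        t = timing.lead_in_trs * timing.tr_s
        for i in range(n):
            row = sub.iloc[i].to_dict()
            row.update(onset=t, duration=timing.image_s, target_side=sides[i])
            out.append(row)
            iti = rng.choice(timing.iti_trs)
            t += timing.image_s + timing.delay_s + timing.go_s + iti * timing.tr_s
    cols = [
        "onset", "duration", "run", "stimulus_type", "category",
        "memory_status", "evidence", "image_type", "target_side",
    ]
    return TrialSchedule(
        pd.DataFrame(out)[cols], session="retrieval", tr_s=timing.tr_s, timing=timing
    )


def assign_groups(n_subjects: int = 24, seed: int = 0) -> list[SubjectDesign]:
    """Assign subjects to the two counterbalanced mapping groups, half each."""
    if n_subjects % 2:
        raise ValueError("n_subjects must be even for counterbalancing")
    rng = np.random.default_rng(seed)
    groups = np.array(["A1"] * (n_subjects // 2) + ["A2"] * (n_subjects // 2))
    rng.shuffle(groups)
    return [
        SubjectDesign(subject_id=i, group=g, mapping=dict(GROUP_MAPPINGS[g]))
        for i, g in enumerate(groups)
    ]


# ---------------------------------------------------------------------------
# Observer
# ---------------------------------------------------------------------------

#: Default accuracy table, status x evidence -> P(choice == true status).
#: Low-evidence old items sit at chance while low-evidence lures remain
#: somewhat discriminable, mirroring typical recognition behavior for this
#: design; middle/high levels are symmetric across status.
DEFAULT_P_CORRECT = {
    ("old", "low"): 0.50,
    ("new", "low"): 0.65,
    ("old", "middle"): 0.75,
    ("new", "middle"): 0.75,
    ("old", "high"): 0.87,
    ("new", "high"): 0.87,
}


def simulate_observer(
    schedule: TrialSchedule,
    design: SubjectDesign,
    p_correct: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> TrialSchedule:
    """Fill choices/responses by sampling Bernoulli accuracy per trial.

    The choice equals the true memory status with probability
    ``p_correct[(status, evidence)]`` and is flipped otherwise; the motor
    response follows the subject's choice->effector mapping.
    """
    p_correct = DEFAULT_P_CORRECT if p_correct is None else p_correct
    for p in p_correct.values():
        if not 0.0 <= p <= 1.0:
            raise ValueError("p_correct entries must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    frame = schedule.frame.copy()
    p = np.array(
        [p_correct[(s, e)] for s, e in zip(frame["memory_status"], frame["evidence"])]
    )
    correct = rng.random(len(frame)) < p
    flip = {"old": "new", "new": "old"}
    frame["choice"] = [
        s if c else flip[s] for s, c in zip(frame["memory_status"], correct)
    ]
    frame["response"] = [design.response_for(c) for c in frame["choice"]]
    frame["correct"] = correct
    return TrialSchedule(frame, schedule.session, schedule.tr_s, schedule.timing)


def behavioral_table(schedules: dict[int, TrialSchedule], designs: list[SubjectDesign]) -> pd.DataFrame:
    """Aggregate per-subject accuracies into one row per status x evidence cell."""
    by_id = {d.subject_id: d for d in designs}
    rows = []
    for sid, sched in schedules.items():
        g = sched.frame.groupby(["memory_status", "evidence"])["correct"].mean()
        for (status, ev), acc in g.items():
            rows.append(
                {
                    "subject_id": sid,
                    "group": by_id[sid].group,
                    "memory_status": status,
                    "evidence": ev,
                    "accuracy": float(acc),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Behavioral mixed ANOVA
# ---------------------------------------------------------------------------

def mixed_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Three-way mixed ANOVA: status and evidence within, group between.

    Expects one accuracy per subject x memory_status x evidence cell in a
    balanced design and partitions sums of squares per the standard
    split-plot decomposition: the between-subject factor is tested against
    subjects-within-groups; each within-subject effect (and its interaction
    with group) against its own factor-by-subject error stratum.

    Returns a table with columns effect, ss, df1, df2, F, p.
    """
    required = {"subject_id", "group", "memory_status", "evidence", "accuracy"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    statuses = sorted(table["memory_status"].unique())
    evidences = sorted(table["evidence"].unique())
    groups = sorted(table["group"].unique())
    subjects = sorted(table["subject_id"].unique())
    a, b, g = len(statuses), len(evidences), len(groups)

    counts = table.groupby(["subject_id", "memory_status", "evidence"]).size()
    if (counts != 1).any() or len(counts) != len(subjects) * a * b:
        raise ValueError("design must be balanced with one observation per cell")
    grp_of = table.groupby("subject_id")["group"].first()
    n_per_group = grp_of.value_counts()
    if n_per_group.nunique() != 1:
        raise ValueError("groups must have equal subject counts")
    n = int(n_per_group.iloc[0])

    # y[group, subject-within-group, status, evidence]
    y = np.empty((g, n, a, b))
    sub_by_group = {gr: sorted(grp_of[grp_of == gr].index) for gr in groups}
    idx = table.set_index(["subject_id", "memory_status", "evidence"])["accuracy"]
    for gi, gr in enumerate(groups):
        for si, sid in enumerate(sub_by_group[gr]):
            for ai, st in enumerate(statuses):
                for bi, ev in enumerate(evidences):
                    y[gi, si, ai, bi] = idx[(sid, st, ev)]

    m = y.mean()
    m_g = y.mean(axis=(1, 2, 3))
    m_gs = y.mean(axis=(2, 3))
    m_a = y.mean(axis=(0, 1, 3))
    m_b = y.mean(axis=(0, 1, 2))
    m_ga = y.mean(axis=(1, 3))
    m_gb = y.mean(axis=(1, 2))
    m_ab = y.mean(axis=(0, 1))
    m_gsa = y.mean(axis=3)
    m_gsb = y.mean(axis=2)
    m_gab = y.mean(axis=1)

    ss_group = a * b * n * np.sum((m_g - m) ** 2)
    ss_subj = a * b * np.sum((m_gs - m_g[:, None]) ** 2)
    ss_status = b * g * n * np.sum((m_a - m) ** 2)
    ss_sxg = b * n * np.sum((m_ga - m_g[:, None] - m_a[None, :] + m) ** 2)
    ss_err_s = b * np.sum(
        (m_gsa - m_gs[:, :, None] - m_ga[:, None, :] + m_g[:, None, None]) ** 2
    )
    ss_evid = a * g * n * np.sum((m_b - m) ** 2)
    ss_exg = a * n * np.sum((m_gb - m_g[:, None] - m_b[None, :] + m) ** 2)
    ss_err_e = a * np.sum(
        (m_gsb - m_gs[:, :, None] - m_gb[:, None, :] + m_g[:, None, None]) ** 2
    )
    ss_sxe = g * n * np.sum(
        (m_ab - m_a[:, None] - m_b[None, :] + m) ** 2
    )
    ss_sxexg = n * np.sum(
        (
            m_gab
            - m_ga[:, :, None]
            - m_gb[:, None, :]
            - m_ab[None, :, :]
            + m_g[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - m
        )
        ** 2
    )
    ss_total = np.sum((y - m) ** 2)
    ss_err_se = ss_total - (
        ss_group + ss_subj + ss_status + ss_sxg + ss_err_s
        + ss_evid + ss_exg + ss_err_e + ss_sxe + ss_sxexg
    )

    df_subj = g * (n - 1)
    rows = []
    eps = 1e-12 * max(float(np.sum(y**2)), 1.0)  # rounding floor for SS

    def add(effect, ss, df1, ss_err, df2):
        ss = 0.0 if ss < eps else float(ss)
        ss_err = 0.0 if ss_err < eps else float(ss_err)
        ms, mse = ss / df1, ss_err / df2
        F = ms / mse if mse > 0 else (0.0 if ss == 0 else np.inf)
        p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        if F == 0.0:
            p = 1.0
        rows.append(dict(effect=effect, ss=ss, df1=df1, df2=df2, F=F, p=p))

    add("group", ss_group, g - 1, ss_subj, df_subj)
    add("memory_status", ss_status, a - 1, ss_err_s, (a - 1) * df_subj)
    add("memory_status:group", ss_sxg, (a - 1) * (g - 1), ss_err_s, (a - 1) * df_subj)
    add("evidence", ss_evid, b - 1, ss_err_e, (b - 1) * df_subj)
    add("evidence:group", ss_exg, (b - 1) * (g - 1), ss_err_e, (b - 1) * df_subj)
    add("memory_status:evidence", ss_sxe, (a - 1) * (b - 1), ss_err_se, (a - 1) * (b - 1) * df_subj)
    add(
        "memory_status:evidence:group",
        ss_sxexg,
        (a - 1) * (b - 1) * (g - 1),
        ss_err_se,
        (a - 1) * (b - 1) * df_subj,
    )
    return pd.DataFrame(rows)


def posthoc_pairwise(table: pd.DataFrame, factor: str = "evidence") -> pd.DataFrame:
    """Pairwise paired t-tests across levels of a within factor, Holm-corrected."""
    from statsmodels.stats.multitest import multipletests

    means = table.groupby(["subject_id", factor])["accuracy"].mean().unstack()
    pairs = list(itertools.combinations(means.columns, 2))
    stats_rows = []
    for x1, x2 in pairs:
        t, p = stats.ttest_rel(means[x1], means[x2])
        stats_rows.append(dict(level_a=x1, level_b=x2, t=float(t), p=float(p)))
    out = pd.DataFrame(stats_rows)
    out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out
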