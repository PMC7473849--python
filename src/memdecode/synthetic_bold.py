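"""Forward simulation of multi-subject BOLD data with planted, locally
distributed, condition-dependent activity patterns.

The generator reproduces the qualitative taxonomy of decision signals the
analysis pipeline is built to dissociate:

* a **choice** pattern — shared across subjects, early and transient,
  amplitude-scaled by decision evidence;
* an **action** pattern — shared, late and sustained until the go-signal;
* an **association** pattern — late, driven by the choice, but carried by a
  spatial code specific to each subject (and signed by the subject's
  choice->response mapping group), so it is invisible to between-subject
  decoding of either choice or action while remaining decodable within
  subject;
* **image-type** and **target-side** patterns — early visual covariates.

Each pattern is a fixed set of neighboring in-mask voxels with zero-mean,
unit-norm weights (so decoding must use the spatial distribution of
activity, not its mean level); its trial-wise amplitude is a signed driver
(+1/-1 from the trial's condition) times a base amplitude, an evidence
gain, and a group sign, convolved with the HRF on the TR grid. Noise is
polynomial drift plus AR(1)-filtered Gaussian noise per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glm import Hrf, event_regressor
from .study_design import SubjectDesign, TrialSchedule

__all__ = [
    "VolumeGrid",
    "PatternSpec",
    "NoiseModel",
    "SubjectDataset",
    "default_pattern_suite",
    "simulate_subject",
    "DRIVERS",
]


@dataclass
class VolumeGrid:
    """Voxel grid with an analysis mask; data arrays are frames x in-mask voxels."""

    dims: tuple[int, int, int]
    voxel_size_mm: float = 3.0
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.dims, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.dims):
            raise ValueError("mask shape must equal dims")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @classmethod
    def ellipsoid(cls, dims: tuple[int, int, int] = (20, 20, 20), voxel_size_mm: float = 3.0) -> "VolumeGrid":
        """Ellipsoidal mask inscribed in the box, one voxel of margin."""
        dims = tuple(dims)
        c = [(d - 1) / 2.0 for d in dims]
        r = [max(d / 2.0 - 1.0, 1.0) for d in dims]
        ii, jj, kk = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
        mask = (
            ((ii - c[0]) / r[0]) ** 2 + ((jj - c[1]) / r[1]) ** 2 + ((kk - c[2]) / r[2]) ** 2
        ) <= 1.0
        return cls(dims, voxel_size_mm, mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def coords(self) -> np.ndarray:
        """In-mask voxel coordinates, n_voxels x 3, in mask order."""
        return np.array(np.nonzero(self.mask)).T

    @property
    def voxel_id_volume(self) -> np.ndarray:
        """3D volume mapping each voxel to its in-mask index (-1 outside)."""
        vol = np.full(self.dims, -1, dtype=int)
        vol[self.mask] = np.arange(self.n_voxels)
        return vol

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.dims, fill, dtype=float)
        vol[self.mask] = values
        return vol


#: Trial condition -> signed driver in {-1, +1}.
DRIVERS = {
    "choice": lambda t: 1.0 if t["choice"] == "old" else -1.0,
    "status": lambda t: 1.0 if t["memory_status"] == "old" else -1.0,
    "response": lambda t: 1.0 if t["response"] == "eye" else -1.0,
    "image_type": lambda t: 1.0 if t["image_type"] == "indoor" else -1.0,
    "target_side": lambda t: 1.0 if t["target_side"] == "left" else -1.0,
}

_UNIT_GAIN = {"low": 1.0, "middle": 1.0, "high": 1.0}
_UNIT_SIGN = {"A1": 1.0, "A2": 1.0}


@dataclass
class PatternSpec:
    """One planted activity pattern.

    ``voxel_ids`` index the grid's in-mask voxel axis; ``weights`` (same
    length, unit L2 norm, zero mean by construction in the default suite)
    define the spatial code. The trial amplitude is
    ``amplitude * evidence_gain[ev] * group_sign[group] * driver(trial)``
    and enters the BOLD as a rectangle of ``duration_s`` starting
    ``onset_lag_s`` after image onset, convolved with the HRF.
    """

    name: str
    voxel_ids: np.ndarray
    weights: np.ndarray
    driver: str
    amplitude: float = 1.0
    evidence_gain: dict[str, float] = field(default_factory=lambda: dict(_UNIT_GAIN))
    onset_lag_s: float = 0.0
    duration_s: float = 2.0
    group_sign: dict[str, float] = field(default_factory=lambda: dict(_UNIT_SIGN))
    #: If True the spatial weights are re-drawn per subject (seeded by the
    #: subject id on the same voxel set), modeling a code that is specific
    #: to each subject's learned choice->response association and therefore
    #: invisible to any between-subject decoder.
    idiosyncratic: bool = False
    weight_seed: int = 0
    #: Fraction of the event amplitude applied as a negative copy delayed
    #: by one event duration — offset suppression that terminates the BOLD
    #: footprint of a transient signal instead of letting the gamma
    #: kernel's tail linger through the late delay period.
    undershoot: float = 0.0

    def subject_weights(self, subject_id: int) -> np.ndarray:
        if not self.idiosyncratic:
            return self.weights
        rng = np.random.default_rng([self.weight_seed, int(subject_id)])
        w = rng.standard_normal(len(self.voxel_ids))
        w -= w.mean()
        return w / np.linalg.norm(w)

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.voxel_ids.shape != self.weights.shape:
            raise ValueError("voxel_ids and weights must have equal length")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.driver not in DRIVERS:
            raise ValueError(f"unknown driver {self.driver!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Per-voxel noise: polynomial drift + AR(1)-filtered white noise."""

    white_sd: float = 1.0
    ar1_coefficient: float = 0.3
    drift_order: int = 1
    drift_sd: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in [0, 1)")


@dataclass
class SubjectDataset:
    """One subject's masked BOLD runs plus design metadata."""

    design: SubjectDesign
    grid: VolumeGrid
    runs: list[np.ndarray]  # each frames x n_voxels
    tr_s: float
    schedule: TrialSchedule

    @property
    def data(self) -> np.ndarray:
        """All runs concatenated along the frame axis."""
        return np.concatenate(self.runs, axis=0)


def _pick_sites(
    grid: VolumeGrid, n_sites: int, site_radius: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Choose disjoint compact voxel sets (balls of ``site_radius``) in the mask."""
    coords = grid.coords
    vol = grid.voxel_id_volume
    taken = np.zeros(grid.n_voxels, dtype=bool)
    sites: list[np.ndarray] = []
    order = rng.permutation(grid.n_voxels)
    offs = [
        (i, j, k)
        for i in range(-site_radius, site_radius + 1)
        for j in range(-site_radius, site_radius + 1)
        for k in range(-site_radius, site_radius + 1)
        if i * i + j * j + k * k <= site_radius**2
    ]
    for center in order:
        if len(sites) == n_sites:
            break
        c = coords[center]
        ids = []
        for o in offs:
            p = c + o
            if np.all(p >= 0) and np.all(p < grid.dims):
                v = vol[tuple(p)]
                if v >= 0:
                    ids.append(v)
        ids = np.array(sorted(ids))
        # require a reasonably complete ball and no overlap with earlier sites
        if len(ids) < 0.7 * len(offs) or taken[ids].any():
            continue
        taken[ids] = True
        sites.append(ids)
    if len(sites) < n_sites:
        raise ValueError(
            f"mask too small to place {n_sites} disjoint pattern sites of radius {site_radius}"
        )
    return sites


def default_pattern_suite(
    grid: VolumeGrid,
    seed: int = 0,
    amplitude: float = 3.0,
    site_radius: int = 2,
) -> list[PatternSpec]:
    """The five-pattern suite matching the study's signal taxonomy.

    Sites are mutually disjoint balls of ``site_radius`` voxels placed at
    seeded random in-mask locations. The choice pattern is early (lag 0,
    ~2 s) with evidence gains 0.5/1.0/1.5 (low/middle/high); action and
    association patterns are late (lag 6 s) and sustained to the
    go-signal; the association pattern's sign follows the subject's
    mapping group, +1 for A1 and -1 for A2.
    """
    rng = np.random.default_rng(seed)
    sites = _pick_sites(grid, 5, site_radius, rng)

    def weights(n):
        w = rng.standard_normal(n)
        w -= w.mean()  # zero-mean: information lives in the distribution
        return w / np.linalg.norm(w)

    late = dict(onset_lag_s=6.0, duration_s=3.5)
    specs = [
        PatternSpec(
            "choice", sites[0], weights(len(sites[0])), "choice",
            amplitude=amplitude, onset_lag_s=0.0, duration_s=2.0,
            evidence_gain={"low": 0.5, "middle": 1.0, "high": 1.5},
            undershoot=0.4,
        ),
        PatternSpec(
            "action", sites[1], weights(len(sites[1])), "response",
            amplitude=amplitude, **late,
        ),
        PatternSpec(
            "association", sites[2], weights(len(sites[2])), "choice",
            amplitude=amplitude, group_sign={"A1": 1.0, "A2": -1.0},
            idiosyncratic=True, weight_seed=seed, **late,
        ),
        PatternSpec(
            "image_type", sites[3], weights(len(sites[3])), "image_type",
            amplitude=amplitude, onset_lag_s=0.0, duration_s=2.0,
        ),
        PatternSpec(
            "target_side", sites[4], weights(len(sites[4])), "target_side",
            amplitude=amplitude, onset_lag_s=0.0, duration_s=2.0,
        ),
    ]
    return specs


def _ar1_noise(shape: tuple[int, int], noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import lfilter

    white = rng.standard_normal(shape) * noise.white_sd
    if noise.ar1_coefficient == 0.0:
        return white
    return lfilter([1.0], [1.0, -noise.ar1_coefficient], white, axis=0)


def simulate_subject(
    design: SubjectDesign,
    schedule: TrialSchedule,
    specs: list[PatternSpec],
    noise: NoiseModel | None = None,
    hrf: Hrf | None = None,
    grid: VolumeGrid | None = None,
    seed: int = 0,
) -> SubjectDataset:
    """Generate one subject's masked 4D BOLD runs from the forward model.

    The schedule must already contain observer choices/responses (the
    choice and response drivers read them). Deterministic for a fixed
    argument tuple.
    """
    if "choice" not in schedule.frame.columns:
        raise ValueError("schedule lacks choices; run simulate_observer first")
    grid = grid or VolumeGrid.ellipsoid()
    noise = noise or NoiseModel()
    kern = (hrf or Hrf()).kernel(schedule.tr_s)
    n_vox = grid.n_voxels
    for spec in specs:
        if spec.voxel_ids.size and (spec.voxel_ids.min() < 0 or spec.voxel_ids.max() >= n_vox):
            raise ValueError(f"pattern {spec.name!r} has out-of-mask voxel ids")

    rng = np.random.default_rng(seed)
    runs = []
    for r in schedule.runs:
        sub = schedule.frame[schedule.frame["run"] == r]
        m = schedule.run_frames(r)
        data = np.zeros((m, n_vox))
        for spec in specs:
            drv = DRIVERS[spec.driver]
            amps = np.array(
                [
                    spec.amplitude
                    * spec.evidence_gain.get(t.get("evidence", "middle"), 1.0)
                    * spec.group_sign.get(design.group, 1.0)
                    * drv(t)
                    for t in sub.to_dict("records")
                ]
            )
            reg = event_regressor(
                sub["onset"].to_numpy() + spec.onset_lag_s,
                spec.duration_s, m, schedule.tr_s, kern, amplitudes=amps,
            )
            if spec.undershoot:
                reg -= spec.undershoot * event_regressor(
                    sub["onset"].to_numpy() + spec.onset_lag_s + spec.duration_s,
                    spec.duration_s, m, schedule.tr_s, kern, amplitudes=amps,
                )
            data[:, spec.voxel_ids] += np.outer(reg, spec.subject_weights(design.subject_id))
        # nuisance: polynomial drift with random per-voxel coefficients
        if noise.drift_sd > 0 and noise.drift_order > 0:
            t = np.linspace(-1.0, 1.0, m)
            basis = np.column_stack([t**k for k in range(1, noise.drift_order + 1)])
            coef = rng.standard_normal((noise.drift_order, n_vox)) * noise.drift_sd
            data += basis @ coef
        if noise.white_sd > 0:
            data += _ar1_noise((m, n_vox), noise, rng)
        runs.append(data)
    return SubjectDataset(design, grid, runs, schedule.tr_s, schedule)
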