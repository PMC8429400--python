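"""Seeded synthetic inputs for every pipeline stage.

Each generator takes an explicit spec (ground truth + noise model) and a
seed, draws from a single local RNG stream, and emits a table that
validates against the consuming module's input schema.  Identical
(spec, seed) pairs are byte-reproducible.

Default noise levels — calibration CV 2 %, time-course noise equivalent to
0.02 pH, per-cell pH SD 0.15, lectin spot CV 10 % — are chosen so that the
downstream estimators reach their documented power/precision at realistic
sample sizes (thousands of cells, six array replicates); all are
overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics as _kinetics
from .lectin import LectinPanel, default_panel
from .phquant import sigmoid_ratio

__all__ = [
    "SigmoidTruth",
    "CalibrationSpec",
    "CellPopulationSpec",
    "TimecourseSpec",
    "LectinArraySpec",
    "gen_calibration",
    "gen_cell_population",
    "gen_timecourse",
    "gen_lectin_arrays",
]

#: the six in-situ calibration buffer pH values
CALIBRATION_PH_GRID = (5.0, 5.5, 6.0, 6.5, 7.0, 7.5)


@dataclass(frozen=True)
class SigmoidTruth:
    """Ground-truth ratio-vs-pH response used by all ratio generators."""

    r_min: float = 0.4
    r_max: float = 2.4
    midpoint_ph: float = 6.3
    hill_slope: float = 1.0

    def ratio(self, ph):
        return sigmoid_ratio(ph, self.r_min, self.r_max, self.midpoint_ph, self.hill_slope)


@dataclass(frozen=True)
class CalibrationSpec:
    sigmoid: SigmoidTruth = SigmoidTruth()
    ph_grid: tuple[float, ...] = CALIBRATION_PH_GRID
    cv: float = 0.02
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass(frozen=True)
class CellPopulationSpec:
    """Single-cell population: expression-linked pH, optionally bimodal.

    In the unimodal case pH = intercept + slope * AU + N(0, ph_sd).  With
    ``bimodal=True`` the pH is drawn from a two-component Gaussian mixture
    (``component_means/sds/weights``) independent of expression.
    """

    n_cells: int = 2000
    au_lo: float = 200.0
    au_hi: float = 5000.0
    au_log_mean: float = 7.3  # log-AU location of the expression distribution
    au_log_sd: float = 0.6
    intercept: float = 6.27
    slope: float = 1.46e-4  # pH per AU; spans ~0.7 pH over the AU range
    ph_sd: float = 0.15
    bimodal: bool = False
    component_means: tuple[float, ...] = (6.5, 7.1)
    component_sds: tuple[float, ...] = (0.1, 0.1)
    component_weights: tuple[float, ...] = (0.5, 0.5)
    sigmoid: SigmoidTruth = SigmoidTruth()

    def __post_init__(self) -> None:
        if self.ph_sd < 0:
            raise ValueError("ph_sd must be non-negative")
        if self.bimodal and abs(sum(self.component_weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")


@dataclass(frozen=True)
class TimecourseSpec:
    """pH time course: closed-form exponential or a kinetic preset replay.

    With ``kinetic_preset`` unset, pH(t) = p_inf + (p0 - p_inf) exp(-k t).
    Otherwise the course is produced by the kinetics simulator under the
    named preset and a permeabilized acidification/CMA protocol
    (``protocol="acidify"`` or ``"cma"``).  Sampling every ``dt_s`` seconds;
    the pH path is pushed through the truth sigmoid and noised with
    additive ratio noise equivalent to ``ph_noise_sd`` pH units.
    """

    p0: float = 7.0
    p_inf: float = 5.2
    k: float = 1.0  # per minute
    t_end: float = 10.0  # minutes
    dt_s: float = 15.0
    ph_noise_sd: float = 0.02
    kinetic_preset: str | None = None
    protocol: str = "acidify"
    bath: str = "cl_hco3"
    sigmoid: SigmoidTruth = SigmoidTruth()

    def __post_init__(self) -> None:
        if self.ph_noise_sd < 0:
            raise ValueError("ph_noise_sd must be non-negative")


@dataclass(frozen=True)
class LectinArraySpec:
    """Two-condition lectin arrays with planted fold changes on condition B.

    Base intensity per lectin is log-normal; every spot gets multiplicative
    noise of coefficient-of-variation ``cv``.  ``fold_map`` multiplies the
    named lectins' condition-B level by the given factor.
    """

    panel: LectinPanel = field(default_factory=default_panel)
    n_replicates: int = 6
    n_spots: int = 6
    base_log_mean: float = 8.0
    base_log_sd: float = 0.8
    cv: float = 0.10
    fold_map: dict[str, float] = field(default_factory=dict)
    condition_a: str = "control"
    condition_b: str = "treated"

    def __post_init__(self) -> None:
        unknown = set(self.fold_map) - set(self.panel.names)
        if unknown:
            raise ValueError(f"fold_map keys not in panel: {sorted(unknown)}")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


# ---------------------------------------------------------------------------
# generators


def gen_calibration(spec: CalibrationSpec, seed: int) -> pd.DataFrame:
    """Calibration table (ph, ratio) with multiplicative noise on the ratio."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(spec.replicates):
        for ph in spec.ph_grid:
            ratio = spec.sigmoid.ratio(ph) * (1.0 + spec.cv * rng.standard_normal())
            rows.append((ph, ratio))
    return pd.DataFrame(rows, columns=["ph", "ratio"])


def gen_cell_population(spec: CellPopulationSpec, seed: int) -> pd.DataFrame:
    """Cell table (cell_id, ratio, expression_au, group, true_ph)."""
    rng = np.random.default_rng(seed)
    au = rng.lognormal(spec.au_log_mean, spec.au_log_sd, size=spec.n_cells)
    au = np.clip(au, spec.au_lo, spec.au_hi - 1e-9)
    if spec.bimodal:
        comp = rng.choice(len(spec.component_weights), size=spec.n_cells, p=spec.component_weights)
        ph = np.array(
            [rng.normal(spec.component_means[c], spec.component_sds[c]) for c in comp]
        )
        group = np.where(comp == 0, "low", "high")
    else:
        ph = spec.intercept + spec.slope * au + spec.ph_sd * rng.standard_normal(spec.n_cells)
        group = np.full(spec.n_cells, "all", dtype=object)
    ratio = spec.sigmoid.ratio(ph)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(spec.n_cells)],
            "ratio": ratio,
            "expression_au": au,
            "group": group,
            "true_ph": ph,
        }
    )


def gen_timecourse(spec: TimecourseSpec, seed: int) -> pd.DataFrame:
    """Time-course table (time_min, ratio, true_ph) sampled every dt_s seconds."""
    rng = np.random.default_rng(seed)
    dt_min = spec.dt_s / 60.0
    t = np.arange(0.0, spec.t_end + dt_min / 2, dt_min)
    if spec.kinetic_preset is None:
        ph = spec.p_inf + (spec.p0 - spec.p_inf) * np.exp(-spec.k * t)
    else:
        comp, params, cyto = _kinetics.load_preset(spec.kinetic_preset)
        bath = _kinetics.permeabilized_bath(spec.bath)
        if spec.protocol == "acidify":
            protocol = _kinetics.Protocol(
                [(0.0, "permeabilize", bath), (1e-6, "add_atp", 10.0)]
            )
        elif spec.protocol == "cma":
            acid_bath = _kinetics.permeabilized_bath("anion_free")
            import copy as _copy
            leak_bath = _copy.deepcopy(bath)
            leak_bath.cma_present = True
            leak_bath.atp_mM = 0.0
            t_switch = spec.t_end / 2.0
            protocol = _kinetics.Protocol(
                [
                    (0.0, "permeabilize", acid_bath),
                    (1e-6, "add_atp", 10.0),
                    (t_switch, "set_bath", leak_bath),
                ]
            )
        else:
            raise ValueError(f"unknown protocol {spec.protocol!r}")
        traj = _kinetics.simulate(
            comp, params, protocol, t_end=spec.t_end, dt_out=dt_min, initial_bath=cyto
        )
        t, ph = traj.time_min, traj.ph
    # additive ratio noise equivalent to ph_noise_sd pH units at the local slope
    ratio_clean = spec.sigmoid.ratio(ph)
    dratio_dph = np.gradient(ratio_clean, ph) if np.ptp(ph) > 0 else np.ones_like(ph)
    ratio = ratio_clean + spec.ph_noise_sd * np.abs(dratio_dph) * rng.standard_normal(t.size)
    return pd.DataFrame({"time_min": t, "ratio": ratio, "true_ph": ph})


def gen_lectin_arrays(spec: LectinArraySpec, seed: int) -> pd.DataFrame:
    """Spot table for two conditions with planted fold changes on B."""
    rng = np.random.default_rng(seed)
    if spec.cv == 0:
        warnings.warn(
            "cv=0 produces zero-variance replicates; downstream p-values degenerate",
            stacklevel=2,
        )
    base = rng.lognormal(spec.base_log_mean, spec.base_log_sd, size=len(spec.panel))
    rows = []
    for cond, is_b in ((spec.condition_a, False), (spec.condition_b, True)):
        for rep in range(spec.n_replicates):
            rep_id = f"{cond}_r{rep + 1}"
            for li, lectin in enumerate(spec.panel.names):
                level = base[li] * (spec.fold_map.get(lectin, 1.0) if is_b else 1.0)
                noise = 1.0 + spec.cv * rng.standard_normal(spec.n_spots)
                for si, x in enumerate(np.maximum(level * noise, 0.0)):
                    rows.append((cond, rep_id, lectin, si, x))
    return pd.DataFrame(rows, columns=["condition", "replicate_id", "lectin", "spot_index", "intensity"])
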