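"""Block-design BOLD simulation from a linear neural dynamical system.

The forward model is the standard linear DCM-style generator used in
fMRI network-benchmark studies.  Neural activity z(t) of N coupled
regions follows

    dz/dt = (A z + W u(t)) / sigma

where A holds directed connection strengths off the diagonal
(``A[target, source]``) and negative within-region decay terms on the
diagonal, W routes the external block-design input u(t) (fed to the
first region only by default), and sigma is the neural lag time
constant (50 ms).  BOLD is the convolution of z with a canonical
double-gamma haemodynamic response function plus white Gaussian
thermal noise (mean 0.1, sd 0.9), sampled at the scanner TR (2.2 s).

The module builds the benchmark topologies — homogeneous chain,
two-leg fork, feedback cycles, single-region decay modification —
simulates multi-subject block-design studies, and summarizes the
dependency-network degree scores across subjects and blocks.  It is
also the package's fixture generator: every test input comes from
here.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from . import core
from .core import NegativeMode
from .timeseries import NodeTimeSeries

__all__ = [
    "NetworkModel",
    "Paradigm",
    "SimulatedStudy",
    "build_chain",
    "build_two_leg",
    "build_cycle",
    "apply_decay_factor",
    "generate_input",
    "integrate_neural",
    "double_gamma_hrf",
    "bold_from_neural",
    "simulate_study",
    "study_degree_scores",
    "run_simulation_experiment",
    "SCENARIOS",
]

#: Neural lag time constant, seconds.
DEFAULT_SIGMA = 0.05
#: Thermal-noise parameters of the BOLD measurement.
DEFAULT_NOISE_MEAN = 0.1
DEFAULT_NOISE_SD = 0.9


@dataclass(frozen=True, eq=False)
class NetworkModel:
    """Linear neural network model.

    ``A[target, source]`` holds directed connection strengths in
    [0, 1]; diagonal entries are strictly negative within-region decay
    terms.  ``input_weights`` routes the external input; by convention
    only the first region receives it.
    """

    region_ids: tuple[str, ...]
    A: np.ndarray
    input_weights: np.ndarray
    neural_lag_sigma: float = DEFAULT_SIGMA

    def __init__(
        self,
        region_ids: Sequence[str],
        A: np.ndarray,
        input_weights: np.ndarray,
        neural_lag_sigma: float = DEFAULT_SIGMA,
    ) -> None:
        region_ids = tuple(str(r) for r in region_ids)
        A = np.asarray(A, dtype=float)
        input_weights = np.asarray(input_weights, dtype=float)
        n = len(region_ids)
        if A.shape != (n, n):
            raise ValueError(f"A must be ({n}, {n}), got {A.shape}")
        if np.any(np.diag(A) >= 0):
            raise ValueError("diagonal decay terms must be strictly negative")
        off = A[~np.eye(n, dtype=bool)]
        if np.any((off < 0) | (off > 1)):
            raise ValueError("off-diagonal connection strengths must be in [0, 1]")
        if input_weights.shape != (n,):
            raise ValueError(f"input_weights must have length {n}")
        if np.any(input_weights < 0) or not np.any(input_weights > 0):
            raise ValueError(
                "input_weights must be nonnegative with at least one "
                "positive entry"
            )
        if neural_lag_sigma <= 0:
            raise ValueError("neural_lag_sigma must be positive")
        object.__setattr__(self, "region_ids", region_ids)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "input_weights", input_weights)
        object.__setattr__(self, "neural_lag_sigma", float(neural_lag_sigma))

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


@dataclass(frozen=True)
class Paradigm:
    """Block-design experiment timing.

    Defaults reproduce the benchmark design: 10 task blocks of 22 s
    (10 TRs at TR = 2.2 s) each followed by 22 s of rest, integrated at
    dt = 10 ms.  ``input_scale`` multiplies the stimulus amplitude; 2.0
    doubles the SNR, the convention used for Influenced-Degree runs.
    """

    n_blocks: int = 10
    block_duration: float = 22.0
    rest_duration: float = 22.0
    TR: float = 2.2
    integration_dt: float = 0.01
    input_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("need at least one block")
        if self.integration_dt <= 0 or self.integration_dt > self.TR / 10:
            raise ValueError("integration_dt must be positive and <= TR/10")
        n_tr = self.block_duration / self.TR
        if self.block_duration <= 0 or abs(n_tr - round(n_tr)) > 1e-9:
            raise ValueError("block_duration must be a positive multiple of TR")
        if self.rest_duration < 0:
            raise ValueError("rest_duration must be nonnegative")
        if self.input_scale <= 0:
            raise ValueError("input_scale must be positive")

    @property
    def cycle_duration(self) -> float:
        return self.block_duration + self.rest_duration

    @property
    def total_duration(self) -> float:
        return self.n_blocks * self.cycle_duration

    @property
    def samples_per_cycle(self) -> int:
        """TR samples per block-plus-rest cycle (the per-block panel)."""
        return int(round(self.cycle_duration / self.TR))

    @property
    def stride(self) -> int:
        return int(round(self.TR / self.integration_dt))


@dataclass(frozen=True, eq=False)
class SimulatedStudy:
    """Simulated multi-subject block-design study.

    ``panels[s][b]`` is subject s's BOLD panel for block b: the block's
    TR samples plus the following rest's samples, so each panel has
    enough timepoints for a stable correlation estimate.
    """

    panels: tuple[tuple[NodeTimeSeries, ...], ...]
    model: NetworkModel
    paradigm: Paradigm
    n_subjects: int
    seed: int

    def iter_panels(self) -> Iterator[NodeTimeSeries]:
        for subject in self.panels:
            yield from subject

    @property
    def n_panels(self) -> int:
        return sum(len(s) for s in self.panels)


def _region_labels(n: int) -> list[str]:
    if n <= 26:
        return list(string.ascii_uppercase[:n])
    return [f"R{i}" for i in range(n)]


def build_chain(n_regions: int, strength: float) -> NetworkModel:
    """Open chain A -> B -> ... with uniform connection strength,
    decay -1 on the diagonal, input into the first region."""
    if n_regions < 2:
        raise ValueError("a chain needs at least 2 regions")
    if not 0.0 <= strength <= 1.0:
        raise ValueError(f"strength must be in [0, 1], got {strength}")
    A = -np.eye(n_regions)
    for r in range(1, n_regions):
        A[r, r - 1] = strength
    w = np.zeros(n_regions)
    w[0] = 1.0
    return NetworkModel(_region_labels(n_regions), A, w)


def build_two_leg(strength: float) -> NetworkModel:
    """Fork topology: A drives two parallel chains B->C->D and
    B'->C'->D' with no cross-leg connections."""
    if not 0.0 <= strength <= 1.0:
        raise ValueError(f"strength must be in [0, 1], got {strength}")
    labels = ["A", "B", "C", "D", "B'", "C'", "D'"]
    n = len(labels)
    A = -np.eye(n)
    edges = [("B", "A"), ("C", "B"), ("D", "C"),
             ("B'", "A"), ("C'", "B'"), ("D'", "C'")]
    index = {r: i for i, r in enumerate(labels)}
    for target, source in edges:
        A[index[target], index[source]] = strength
    w = np.zeros(n)
    w[0] = 1.0
    return NetworkModel(labels, A, w)


def build_cycle(
    variant: Literal["single_loop", "double_loop"], strength: float
) -> NetworkModel:
    """Three-region chain A->B->C closed by feedback: C->A
    (``single_loop``) or C->A and C->B (``double_loop``)."""
    if variant not in ("single_loop", "double_loop"):
        raise ValueError(f"unknown cycle variant {variant!r}")
    model = build_chain(3, strength)
    A = model.A.copy()
    A[0, 2] = strength
    if variant == "double_loop":
        A[1, 2] = strength
    return NetworkModel(model.region_ids, A, model.input_weights)


def apply_decay_factor(model: NetworkModel, region, m: float) -> NetworkModel:
    """Divide one region's diagonal decay term by factor m.

    m > 1 slows the within-region decay, prolonging that region's
    activation; m = 1 is the identity.
    """
    if m <= 0:
        raise ValueError(f"decay factor must be positive, got {m}")
    r = core._resolve_indices(model.region_ids, region)
    A = model.A.copy()
    A[r, r] = A[r, r] / m
    return NetworkModel(
        model.region_ids, A, model.input_weights, model.neural_lag_sigma
    )


def generate_input(paradigm: Paradigm) -> np.ndarray:
    """Stimulus time course u(t) on the integration grid:
    ``input_scale`` during task blocks, 0 during rest."""
    dt = paradigm.integration_dt
    n_on = int(round(paradigm.block_duration / dt))
    n_off = int(round(paradigm.rest_duration / dt))
    cycle = np.concatenate(
        [np.full(n_on, paradigm.input_scale), np.zeros(n_off)]
    )
    return np.tile(cycle, paradigm.n_blocks)


def integrate_neural(
    model: NetworkModel, u: np.ndarray, dt: float
) -> np.ndarray:
    """Forward-Euler integration of dz/dt = (A z + W u)/sigma from
    z(0) = 0; returns z with shape (n_regions, len(u))."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    eig = np.linalg.eigvals(model.A)
    if np.any(eig.real >= 0):
        raise ValueError(
            "unstable network: matrix A has an eigenvalue with "
            f"nonnegative real part (max {eig.real.max():.3g})"
        )
    u = np.asarray(u, dtype=float)
    n = model.n_regions
    # one-step transition of the Euler scheme, precomputed
    M = np.eye(n) + (dt / model.neural_lag_sigma) * model.A
    w = (dt / model.neural_lag_sigma) * model.input_weights
    z = np.zeros((n, u.size))
    state = np.zeros(n)
    for t in range(u.size):
        z[:, t] = state
        state = M @ state + w * u[t]
    return z


def double_gamma_hrf(
    dt: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
    duration: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response kernel sampled at dt.

    The kernel holds the raw density-difference samples, so discrete
    convolution sums them directly: the steady-state gain to sustained
    unit input is (kernel area)/dt — about 83 at dt = 10 ms.  Against
    thermal noise of sd 0.9 this leaves upstream regions with strong
    BOLD signal while far-downstream regions (amplitude shrinking as
    strength^k) approach the noise floor, the regime the degree
    measures are validated in.
    """
    t = np.arange(0.0, duration, dt)
    peak = sp_stats.gamma.pdf(t, peak_delay / peak_dispersion,
                              scale=peak_dispersion)
    under = sp_stats.gamma.pdf(t, undershoot_delay / undershoot_dispersion,
                               scale=undershoot_dispersion)
    return peak - undershoot_ratio * under


def bold_from_neural(
    z: np.ndarray,
    dt: float,
    TR: float,
    noise_mean: float = DEFAULT_NOISE_MEAN,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng: np.random.Generator | None = None,
    region_ids: Sequence[str] | None = None,
    hrf: np.ndarray | None = None,
) -> NodeTimeSeries:
    """BOLD panel from neural activity: HRF convolution, additive white
    Gaussian thermal noise, decimation to the scanner TR."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    stride = int(round(TR / dt))
    if abs(TR / dt - stride) > 1e-6:
        raise ValueError(f"TR ({TR}) must be a multiple of dt ({dt})")
    if hrf is None:
        hrf = double_gamma_hrf(dt)
    clean = sp_signal.fftconvolve(z, hrf[None, :], mode="full")[:, : z.shape[1]]
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = clean + rng.normal(noise_mean, noise_sd, size=clean.shape)
    else:
        y = clean + noise_mean
    y = y[:, ::stride]
    if region_ids is None:
        region_ids = _region_labels(z.shape[0])
    return NodeTimeSeries(
        region_ids, y, sampling_interval=TR, require_variance=False
    )


def _subject_seed_sequences(seed: int, n_subjects: int):
    # per-subject streams spawned by index: adding subjects never
    # reshuffles earlier subjects' noise
    return np.random.SeedSequence(seed).spawn(n_subjects)


def simulate_study(
    model: NetworkModel,
    paradigm: Paradigm | None = None,
    n_subjects: int = 20,
    seed: int = 0,
) -> SimulatedStudy:
    """Simulate a full multi-subject study.

    The noise-free neural trajectory and its HRF convolution are shared
    across subjects (the paradigm is identical); each subject receives
    an independent thermal-noise realization.  The run is split into
    per-block panels of ``samples_per_cycle`` TR samples each.
    """
    if paradigm is None:
        paradigm = Paradigm()
    dt = paradigm.integration_dt
    u = generate_input(paradigm)
    z = integrate_neural(model, u, dt)
    hrf = double_gamma_hrf(dt)
    clean = sp_signal.fftconvolve(z, hrf[None, :], mode="full")[:, : z.shape[1]]
    stride = paradigm.stride
    per_block = paradigm.samples_per_cycle

    subjects = []
    for ss in _subject_seed_sequences(seed, n_subjects):
        rng = np.random.default_rng(ss)
        y = clean + rng.normal(
            DEFAULT_NOISE_MEAN, DEFAULT_NOISE_SD, size=clean.shape
        )
        y = y[:, ::stride]
        blocks = tuple(
            NodeTimeSeries(
                model.region_ids,
                y[:, b * per_block : (b + 1) * per_block],
                sampling_interval=paradigm.TR,
                require_variance=False,
            )
            for b in range(paradigm.n_blocks)
        )
        subjects.append(blocks)
    return SimulatedStudy(
        tuple(subjects), model, paradigm, n_subjects, seed
    )


def study_degree_scores(
    study: SimulatedStudy, negative_mode: NegativeMode = "clip_to_zero"
) -> pd.DataFrame:
    """Per-panel degree scores: one row per (subject, block, region,
    measure) with the Influencing and Influenced Degrees of that panel."""
    rows = []
    for s, subject in enumerate(study.panels):
        for b, panel in enumerate(subject):
            _, _, prof = core.depna(panel, negative_mode)
            for r, region in enumerate(panel.node_ids):
                rows.append(
                    (s, b, region, prof.influencing[r], prof.influenced[r])
                )
    return pd.DataFrame(
        rows, columns=["subject", "block", "region", "influencing", "influenced"]
    )


def summarize_degrees(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of each degree measure per region, over all
    subject-block scores."""
    long = scores.melt(
        id_vars=["subject", "block", "region"],
        value_vars=["influencing", "influenced"],
        var_name="measure",
        value_name="score",
    )
    out = (
        long.groupby(["region", "measure"], sort=False)["score"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
        .reset_index()
    )
    return out


SCENARIOS = (
    "chain_sweep",
    "mid_connection_sweep",
    "two_leg",
    "decay_sweep",
    "cycle",
)

_DEFAULT_STRENGTHS = (0.1, 0.2, 0.3, 0.4, 0.5)
_DEFAULT_DECAY_FACTORS = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0)


def _study_summary(model, paradigm, n_subjects, seed, negative_mode):
    scores = study_degree_scores(
        simulate_study(model, paradigm, n_subjects, seed), negative_mode
    )
    return summarize_degrees(scores)


def run_simulation_experiment(
    scenario: str,
    strengths: Sequence[float] | None = None,
    decay_factors: Sequence[float] | None = None,
    decay_region: str = "D",
    fixed_strength: float = 0.4,
    n_subjects: int = 20,
    seed: int = 0,
    paradigm: Paradigm | None = None,
    input_scale_influenced: float = 2.0,
    negative_mode: NegativeMode = "clip_to_zero",
) -> pd.DataFrame:
    """Run one benchmark scenario over its parameter grid.

    Returns a tidy table (scenario, parameter, region, measure, mean,
    sem).  Influencing-Degree rows come from studies at the paradigm's
    nominal input scale; Influenced-Degree rows from studies with the
    input scaled by ``input_scale_influenced`` (default 2, the doubled-
    SNR convention).
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; choose from {SCENARIOS}"
        )
    if paradigm is None:
        paradigm = Paradigm()
    strengths = tuple(strengths) if strengths is not None else _DEFAULT_STRENGTHS
    decay_factors = (
        tuple(decay_factors) if decay_factors is not None
        else _DEFAULT_DECAY_FACTORS
    )

    def models_for(param):
        if scenario == "chain_sweep":
            return build_chain(4, param)
        if scenario == "mid_connection_sweep":
            model = build_chain(4, fixed_strength)
            A = model.A.copy()
            A[2, 1] = param  # the middle connection B -> C
            return NetworkModel(model.region_ids, A, model.input_weights)
        if scenario == "two_leg":
            return build_two_leg(param)
        if scenario == "decay_sweep":
            return apply_decay_factor(
                build_chain(4, fixed_strength), decay_region, param
            )
        if scenario == "cycle":
            if param == "open_chain":
                return build_chain(3, fixed_strength)
            return build_cycle(param, fixed_strength)
        raise AssertionError(scenario)

    if scenario == "decay_sweep":
        grid: Sequence = decay_factors
    elif scenario == "cycle":
        grid = ("open_chain", "single_loop", "double_loop")
    else:
        grid = strengths

    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(2 * len(grid)))
    scaled = replace(
        paradigm, input_scale=paradigm.input_scale * input_scale_influenced
    )
    frames = []
    for param in grid:
        model = models_for(param)
        for measure, pdgm in (("influencing", paradigm), ("influenced", scaled)):
            child = next(children)
            summary = _study_summary(
                model, pdgm, n_subjects,
                int(child.generate_state(1, np.uint32)[0]), negative_mode,
            )
            summary = summary[summary["measure"] == measure].copy()
            summary.insert(0, "parameter", param)
            summary.insert(0, "scenario", scenario)
            frames.append(summary)
    return pd.concat(frames, ignore_index=True)


def plot_experiment(summary: pd.DataFrame, measure: str = "influencing", ax=None):
    """Errorbar plot of mean degree per region across the parameter grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = summary[summary["measure"] == measure]
    for region, grp in sub.groupby("region", sort=False):
        ax.errorbar(
            [str(p) for p in grp["parameter"]],
            grp["mean"], yerr=grp["sem"], label=region, capsize=2,
        )
    ax.set_xlabel("parameter")
    ax.set_ylabel(f"mean {measure} degree")
    ax.legend(title="region")
    return ax
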