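"""Synthetic multichannel time series with paradigm-dependent state structure.

Real task MEG shows time points clustering around recurring whole-brain
activation states, with cognitively demanding paradigms revisiting fewer,
tighter states than relaxed ones. The generator here emulates exactly that
regime with a hidden-state process: per paradigm, a small set of state
centroids is drawn in channel space, a state sequence with geometric
(memoryless) dwell times walks between them, and each time point is its
current centroid plus isotropic noise. This gives every downstream stage
(preprocessing, Mapper, graph analysis, statistics) a testable input
without any real recordings.

The module also packages the printed 60-subject closeness-centrality
worked example as a fixture (``load_table1_fixture``).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .exceptions import DataError, InvalidConfigError, UsageError
from .preprocessing import LabeledTimeSeries
from .stats import PairedSample

logger = logging.getLogger(__name__)

#: Nominal sampling rate attached to synthetic sessions, Hz.
DEFAULT_RATE = 256.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the hidden-state session generator.

    Parameters
    ----------
    n_channels
        Number of simulated channels (columns).
    n_states
        Number of recurring activation states for the paradigm.
    noise_sd
        Within-state isotropic noise scale (sigma_p).
    centroid_scale
        Scale of the zero-mean isotropic distribution the state centroids
        are drawn from (sigma_c).
    mean_dwell
        Mean dwell time in a state, in time points (geometric law).
    n_timepoints
        Number of time points generated for the paradigm block.
    seed
        Seed of the generator; identical (config, seed) gives bit-identical
        output.
    """

    n_channels: int
    n_states: int
    noise_sd: float
    centroid_scale: float
    mean_dwell: float
    n_timepoints: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_states < 1 or self.n_timepoints < 1:
            raise InvalidConfigError("all counts must be >= 1")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if self.centroid_scale <= 0:
            raise InvalidConfigError("centroid_scale must be > 0")
        if self.mean_dwell < 1:
            raise InvalidConfigError("mean_dwell must be >= 1 time point")


def _simulate(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the hidden-state process; returns (data, states, centroids)."""
    rng = np.random.default_rng(config.seed)
    centroids = rng.normal(0.0, config.centroid_scale, size=(config.n_states, config.n_channels))
    switch_p = 1.0 / config.mean_dwell
    states = np.empty(config.n_timepoints, dtype=int)
    s = int(rng.integers(config.n_states))
    for t in range(config.n_timepoints):
        states[t] = s
        if config.n_states > 1 and rng.random() < switch_p:
            # jump to a uniformly chosen different state
            s = (s + 1 + int(rng.integers(config.n_states - 1))) % config.n_states
    noise = rng.normal(0.0, 1.0, size=(config.n_timepoints, config.n_channels))
    data = centroids[states] + config.noise_sd * noise
    return data, states, centroids


def generate_subject_session(
    config: SimulationConfig,
    paradigm_name: str,
    return_states: bool = False,
):
    """Generate one paradigm block as a labeled time series.

    Every time point carries ``paradigm_name`` and phase ``"stimulus"``.
    With ``return_states=True`` the true hidden-state sequence and the
    generating centroids are returned alongside, for oracle checks.
    """
    data, states, centroids = _simulate(config)
    n = config.n_timepoints
    ts = LabeledTimeSeries(
        data=data,
        channel_ids=[f"ch{i:03d}" for i in range(config.n_channels)],
        sampling_rate=DEFAULT_RATE,
        paradigm=np.full(n, paradigm_name, dtype=object),
        phase=np.full(n, "stimulus", dtype=object),
    )
    if return_states:
        return ts, states, centroids
    return ts


def _derive_seed(cohort_seed: int, *keys: int) -> int:
    """Deterministic per-subject seed below 2**31."""
    ss = np.random.SeedSequence([int(cohort_seed), *map(int, keys)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    n_subjects: int,
    demanding_config: SimulationConfig,
    relaxed_config: SimulationConfig,
    seed: int = 0,
    paradigm_names: tuple[str, str] = ("demanding", "relaxed"),
) -> list[LabeledTimeSeries]:
    """Generate a cohort of two-paradigm sessions.

    Each subject's session concatenates a "demanding" block (fewer and/or
    tighter states) followed by a "relaxed" block, with paradigm labels.
    Per-subject seeds are derived deterministically from the cohort seed so
    subjects are independent yet reproducible.
    """
    if n_subjects < 2:
        raise InvalidConfigError("paired tests need at least 2 subjects")
    if (
        demanding_config.n_states > relaxed_config.n_states
        or demanding_config.noise_sd > relaxed_config.noise_sd
    ):
        raise InvalidConfigError(
            "demanding paradigm must not have more states or larger noise than "
            "the relaxed one (identical configs are allowed for null cohorts)"
        )
    if demanding_config.n_channels != relaxed_config.n_channels:
        raise InvalidConfigError("both paradigms must share the channel layout")

    cohort: list[LabeledTimeSeries] = []
    for i in range(n_subjects):
        blocks = []
        for k, (cfg, name) in enumerate(
            zip((demanding_config, relaxed_config), paradigm_names)
        ):
            cfg_i = replace(cfg, seed=_derive_seed(seed, i, k))
            blocks.append(generate_subject_session(cfg_i, name))
        session = LabeledTimeSeries(
            data=np.vstack([b.data for b in blocks]),
            channel_ids=list(blocks[0].channel_ids),
            sampling_rate=DEFAULT_RATE,
            paradigm=np.concatenate([b.paradigm for b in blocks]),
            phase=np.concatenate([b.phase for b in blocks]),
            subject_id=f"sub-{i:03d}",
        )
        cohort.append(session)
    return cohort


def generate_response_times(
    modularity_scores,
    slope: float,
    noise_sd: float,
    seed: int = 0,
    intercept: float = 1.0,
) -> np.ndarray:
    """Response times linearly coupled to modularity: rt = a + b*Q + noise.

    A negative ``slope`` emulates the regime where subjects whose Mapper
    graphs are more modular respond faster.
    """
    q = np.asarray(modularity_scores, dtype=float)
    if q.size == 0:
        raise UsageError("modularity_scores must be nonempty")
    if noise_sd < 0:
        raise UsageError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    return intercept + slope * q + rng.normal(0.0, noise_sd, size=q.shape)


def default_cohort_configs(
    n_channels: int = 32,
    n_timepoints: int = 1000,
    seed: int = 0,
) -> tuple[SimulationConfig, SimulationConfig]:
    """Study-condition configs for a demanding-vs-relaxed cohort.

    The demanding paradigm revisits 3 compact, closely spaced states; the
    relaxed one wanders over 12 widely spaced states at the same
    within-state noise. Fewer and more tightly packed states make the
    demanding paradigm's time points mutually more similar, the mechanism
    through which cognitively demanding tasks acquire higher node
    centrality.
    """
    demanding = SimulationConfig(
        n_channels=n_channels,
        n_states=3,
        noise_sd=0.7,
        centroid_scale=0.5,
        mean_dwell=20.0,
        n_timepoints=n_timepoints,
        seed=seed,
    )
    relaxed = SimulationConfig(
        n_channels=n_channels,
        n_states=12,
        noise_sd=0.7,
        centroid_scale=1.5,
        mean_dwell=20.0,
        n_timepoints=n_timepoints,
        seed=seed,
    )
    return demanding, relaxed


#: Subjects whose rows are bolded (swapped) in the printed worked example.
TABLE1_SWAPPED_SUBJECTS = frozenset({"169040", "257845", "568963"})


def load_table1_fixture() -> PairedSample:
    """Load the packaged 60-subject closeness-centrality worked example.

    Returns the (Wrkmem, Storym) mean-closeness pairs exactly at their
    printed 4-decimal precision. The returned sample carries a
    ``swapped_subjects`` attribute naming the three subjects whose scores
    are swapped to form the illustrative permuted dataset.
    """
    try:
        text = resources.files("megmapper").joinpath("data/table1_closeness.csv").read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise DataError("table1 fixture is missing from the package") from exc
    rows = list(csv.DictReader(text.splitlines()))
    if not rows:
        raise DataError("table1 fixture is empty")
    try:
        subjects = [r["subject"] for r in rows]
        a = np.array([float(r["wrkmem"]) for r in rows])
        b = np.array([float(r["storym"]) for r in rows])
        swapped = {r["subject"] for r in rows if r["swapped_flag"] == "1"}
    except (KeyError, ValueError) as exc:
        raise DataError("table1 fixture is corrupt") from exc
    sample = PairedSample(
        subject_ids=subjects, score_a=a, score_b=b, label_a="Wrkmem", label_b="Storym"
    )
    sample.swapped_subjects = swapped  # type: ignore[attr-defined]
    return sample


def write_session(ts: LabeledTimeSeries, path: str | Path) -> Path:
    """Write a session as a CSV matrix plus a CSV label sidecar.

    ``<path>.csv`` holds the numeric matrix (one column per channel);
    ``<path>.labels.csv`` holds (time_index, paradigm, phase).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix_path = path.with_suffix(".csv")
    header = ",".join(ts.channel_ids)
    np.savetxt(matrix_path, ts.data, delimiter=",", header=header, comments="")
    labels_path = path.with_suffix(".labels.csv")
    with open(labels_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_index", "paradigm", "phase", "subject_id", "sampling_rate"])
        for i in range(ts.n_timepoints):
            w.writerow([i, ts.paradigm[i], ts.phase[i], ts.subject_id, ts.sampling_rate])
    return matrix_path


def read_session(path: str | Path) -> LabeledTimeSeries:
    """Read a session written by :func:`write_session`."""
    path = Path(path)
    matrix_path = path.with_suffix(".csv")
    labels_path = path.with_suffix(".labels.csv")
    if not matrix_path.exists() or not labels_path.exists():
        raise DataError(f"session container incomplete at {path}")
    with open(matrix_path) as fh:
        channel_ids = fh.readline().strip().split(",")
    data = np.loadtxt(matrix_path, delimiter=",", skiprows=1, ndmin=2)
    with open(labels_path) as fh:
        rows = list(csv.DictReader(fh))
    if len(rows) != data.shape[0]:
        raise DataError("label sidecar does not match the matrix row count")
    return LabeledTimeSeries(
        data=data,
        channel_ids=channel_ids,
        sampling_rate=float(rows[0]["sampling_rate"]),
        paradigm=np.array([r["paradigm"] for r in rows], dtype=object),
        phase=np.array([r["phase"] for r in rows], dtype=object),
        subject_id=rows[0]["subject_id"],
    )
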