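"""Synthetic resting-state EEG with planted microstate dynamics.

The generator emulates what the narrowband microstate model assumes the
data look like: at every moment one of a small set of fixed scalp
topographies is active, its amplitude follows a band-limited envelope,
dwell times are right-skewed around the canonical 60-120 ms range, and
state successions follow a semi-Markov chain (gamma dwell times, next
state drawn from the transition row of the current one).  Spatially
smooth Gaussian sensor noise is added at a configurable signal-to-noise
ratio.  Because every quantity the downstream pipeline estimates is
planted explicitly, the generator doubles as ground truth for
parameter-recovery tests.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning: subject i receives child
sequence i, and within a subject the band components draw from further
children in band order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .cluster import canonical_templates, spatial_correlation
from .montage import Montage, default_montage
from .preprocess import BANDS, BandSpec, fir_bandpass
from .recording import EEGRecording, average_reference

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "GroupBandEffect",
    "ScoreCoupling",
    "CohortSpec",
    "Cohort",
    "make_templates",
    "sample_state_sequence",
    "synthesize_eeg",
    "make_cohort",
    "default_cohort_spec",
    "uniform_transition_matrix",
    "concentration_for_sd",
]

STATE_NAMES = ("A", "B", "C", "D")


def uniform_transition_matrix(n_states: int = 4) -> np.ndarray:
    """Zero-diagonal row-stochastic matrix with uniform off-diagonal mass."""
    m = np.full((n_states, n_states), 1.0 / (n_states - 1))
    np.fill_diagonal(m, 0.0)
    return m


def _validate_transition_matrix(tm: np.ndarray) -> np.ndarray:
    tm = np.asarray(tm, dtype=float)
    if tm.ndim != 2 or tm.shape[0] != tm.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(np.diagonal(tm) != 0):
        raise ValueError("transition matrix must have zero diagonal")
    if np.any(tm < 0) or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition rows must be nonnegative and sum to 1")
    return tm


@dataclass
class SyntheticConfig:
    """Parameters of one narrowband microstate signal component."""

    n_channels: int = 52
    sampling_rate: float = 256.0
    duration: float = 20.0
    n_states: int = 4
    transition_matrix: Optional[np.ndarray] = None
    dwell_mean: float = 80.0  # ms
    dwell_shape: float = 4.0
    band: tuple[float, float] = (1.0, 4.0)
    snr: float = 3.0
    amplitude: float = 15.0  # uV scaling of the state signal
    noise_smoothness: float = 0.5  # spatial kernel length (chordal distance)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            self.transition_matrix = uniform_transition_matrix(self.n_states)
        self.transition_matrix = _validate_transition_matrix(self.transition_matrix)
        if self.transition_matrix.shape[0] != self.n_states:
            raise ValueError("transition matrix size must equal n_states")
        if self.dwell_mean <= 0 or self.dwell_shape <= 0:
            raise ValueError("dwell parameters must be positive")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        low, high = self.band
        if not (0 < low < high < self.sampling_rate / 2):
            raise ValueError("band must satisfy 0 < low < high < Nyquist")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


@dataclass
class SyntheticTruth:
    """Planted templates, per-sample state sequence and transition matrix."""

    templates: np.ndarray = field(repr=False)  # (n_states, n_channels)
    state_sequence: np.ndarray = field(repr=False)  # per-sample state index
    transition_matrix: np.ndarray = field(repr=False)
    segments: list[tuple[int, int]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.templates, dtype=float)
        seq = np.asarray(self.state_sequence, dtype=int)
        n_states = t.shape[0]
        for i in range(n_states):
            for j in range(i + 1, n_states):
                if spatial_correlation(t[i], t[j]) >= 0.95:
                    raise ValueError(f"planted templates {i} and {j} are not distinct")
        if seq.size and (seq.min() < 0 or seq.max() >= n_states):
            raise ValueError("state sequence indexes a nonexistent state")
        self.templates = t
        self.state_sequence = seq


def make_templates(
    montage: Montage,
    n_states: int = 4,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.15,
) -> np.ndarray:
    """Average-referenced unit-norm dipolar topographies.

    The first four states perturb the canonical A-D orientations
    (left-diagonal, right-diagonal, anterior-posterior, fronto-central)
    by a seeded smooth random field of relative strength ``jitter``;
    further states are random dipole projections.  Pairs closer than
    |spatial correlation| 0.95 are rejected and redrawn.
    """
    if n_states > montage.n_channels:
        raise ValueError("montage too small for the requested number of states")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = montage.positions
    canon = canonical_templates(montage).maps

    maps: list[np.ndarray] = []
    for i in range(n_states):
        for _attempt in range(100):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            base = canon[i] if i < 4 else p @ u
            t = base + (jitter if i < 4 else 0.0) * (p @ rng.standard_normal(3))
            t = t - t.mean()
            norm = np.linalg.norm(t)
            if norm == 0:
                continue
            t /= norm
            if all(abs(float(np.dot(t, m))) < 0.95 for m in maps):
                maps.append(t)
                break
        else:
            raise RuntimeError("could not draw mutually distinct templates")
    return np.stack(maps)


def sample_state_sequence(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Semi-Markov state sequence: (per-sample labels, [(state, n_samples)]).

    Dwell times are gamma distributed (mean ``dwell_mean`` ms, shape
    ``dwell_shape``), floored at one sample; each segment's state is
    drawn from the transition row of its predecessor, so consecutive
    segments always differ.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_samples
    fs = config.sampling_rate
    scale_ms = config.dwell_mean / config.dwell_shape
    tm = config.transition_matrix

    segments: list[tuple[int, int]] = []
    labels = np.empty(n, dtype=int)
    pos = 0
    state = int(rng.integers(config.n_states))
    while pos < n:
        dwell_ms = rng.gamma(config.dwell_shape, scale_ms)
        length = max(1, int(round(dwell_ms * fs / 1000.0)))
        length = min(length, n - pos)
        labels[pos : pos + length] = state
        segments.append((state, length))
        pos += length
        state = int(rng.choice(config.n_states, p=tm[state]))
    return labels, segments


def _band_envelope(n: int, band: tuple[float, float], fs: float, rng: np.random.Generator) -> np.ndarray:
    """Rectified magnitude of a band-limited unit-variance process."""
    taps = fir_bandpass(band[0], band[1], fs)
    pad = len(taps)
    white = rng.standard_normal(n + 2 * pad)
    x = sp_signal.filtfilt(taps, [1.0], white, padlen=min(3 * len(taps), white.size - 1))
    x = x[pad:-pad]
    sd = x.std()
    if sd == 0:
        raise RuntimeError("degenerate envelope")
    return np.abs(x / sd)


def _smooth_noise(montage: Montage, n: int, smoothness: float, rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated Gaussian sensor noise (unit marginal variance)."""
    p = montage.positions
    d2 = np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=-1)
    k = np.exp(-d2 / (2.0 * smoothness**2))
    chol = np.linalg.cholesky(k + 1e-9 * np.eye(len(p)))
    return chol @ rng.standard_normal((len(p), n))


def synthesize_eeg(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    montage: Optional[Montage] = None,
    rng: Optional[np.random.Generator] = None,
    subject_id: str = "s0",
    group: str = "synthetic",
    return_parts: bool = False,
):
    """Render ``signal(t) = envelope(t) * template[state(t)] + noise(t)``.

    The envelope is the rectified magnitude of a band-limited
    unit-variance process in the configured band; noise is spatially
    smooth Gaussian scaled so signal RMS / noise RMS equals the
    configured SNR (``snr=inf`` means noiseless).  The output is
    average-referenced.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    montage = montage if montage is not None else default_montage(config.n_channels)
    if truth.templates.shape[1] != montage.n_channels:
        raise ValueError("template channel count does not match montage")
    n = truth.state_sequence.size

    env = _band_envelope(n, config.band, config.sampling_rate, rng)
    sig = config.amplitude * env[None, :] * truth.templates[truth.state_sequence].T
    sig_rms = np.sqrt(np.mean(sig**2))
    if np.isinf(config.snr):
        noise = np.zeros_like(sig)
    else:
        noise = _smooth_noise(montage, n, config.noise_smoothness, rng)
        noise *= sig_rms / (config.snr * np.sqrt(np.mean(noise**2)))
    data = average_reference(sig + noise)
    rec = EEGRecording(data, config.sampling_rate, montage, subject_id=subject_id, group=group)
    if return_parts:
        return rec, sig, noise
    return rec


# ---------------------------------------------------------------------------
# cohort generation


def concentration_for_sd(mean: float, sd: float) -> float:
    """Dirichlet concentration giving entry variance mean(1-mean)/(c+1) = sd^2."""
    if not (0 < mean < 1 and sd > 0):
        raise ValueError("need 0 < mean < 1 and sd > 0")
    c = mean * (1.0 - mean) / sd**2 - 1.0
    if c <= 0:
        raise ValueError("target sd too large for a Dirichlet row")
    return c


@dataclass
class GroupBandEffect:
    """Group-level mean transition matrix and per-row Dirichlet concentration."""

    mean_tp: np.ndarray
    concentration: np.ndarray  # (n_states,)

    def __post_init__(self) -> None:
        self.mean_tp = _validate_transition_matrix(self.mean_tp)
        self.concentration = np.broadcast_to(
            np.asarray(self.concentration, dtype=float), (self.mean_tp.shape[0],)
        ).copy()
        if np.any(self.concentration <= 0):
            raise ValueError("concentrations must be positive")


@dataclass
class ScoreCoupling:
    """Monotone coupling of a clinical score to one planted transition entry.

    ``score = loc + spread * (rho * z(entry) + sqrt(1 - rho^2) * noise)``
    where z is the standardized planted entry over patients; |rho| is the
    target Spearman magnitude (exact at |rho| = 1).
    """

    scale: str  # "VAS" or "ABC"
    band: str
    from_state: int
    to_state: int
    rho: float
    loc: float
    spread: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")


@dataclass
class CohortSpec:
    """Per-group, per-band planted dynamics plus score couplings."""

    groups: dict[str, dict[str, GroupBandEffect]]
    couplings: list[ScoreCoupling]
    dhi_ranges: dict[str, tuple[float, float]]
    patient_groups: tuple[str, ...] = ("MD", "SV")


def default_cohort_spec(bands: Sequence[str] = ("delta", "theta", "alpha", "beta")) -> CohortSpec:
    """The shipped study conditions.

    The delta band plants the severity effect in the C->B transition
    (MD mean 0.383, SD 0.104; SV mean 0.162, SD 0.040); all other rows
    and bands are uniform with moderate between-subject variability.
    VAS is coupled negatively and ABC positively to the planted delta
    C->B entry.
    """
    a, b, c, d = 0, 1, 2, 3
    base_conc = 60.0

    def uniform_effect() -> GroupBandEffect:
        return GroupBandEffect(uniform_transition_matrix(4), np.full(4, base_conc))

    def delta_effect(cb_mean: float, cb_sd: float) -> GroupBandEffect:
        tm = uniform_transition_matrix(4)
        rest = (1.0 - cb_mean) / 2.0
        tm[c] = 0.0
        tm[c, b] = cb_mean
        tm[c, a] = rest
        tm[c, d] = rest
        conc = np.full(4, base_conc)
        conc[c] = concentration_for_sd(cb_mean, cb_sd)
        return GroupBandEffect(tm, conc)

    groups = {}
    for g in ("HC", "MD", "SV"):
        groups[g] = {band: uniform_effect() for band in bands}
    if "delta" in bands:
        groups["MD"]["delta"] = delta_effect(0.383, 0.104)
        groups["SV"]["delta"] = delta_effect(0.162, 0.040)

    couplings = [
        ScoreCoupling("VAS", "delta", c, b, -0.66, loc=5.0, spread=2.0),
        ScoreCoupling("ABC", "delta", c, b, 0.69, loc=60.0, spread=15.0),
    ]
    dhi = {"HC": (0.0, 14.0), "MD": (20.0, 60.0), "SV": (61.0, 100.0)}
    return CohortSpec(groups, couplings, dhi)


@dataclass
class Cohort:
    """Synthesized recordings plus clinical table and planted ground truth."""

    recordings: list[EEGRecording]
    clinical: pd.DataFrame
    truths: dict[str, dict[str, SyntheticTruth]]  # subject -> band -> truth
    templates: dict[str, np.ndarray]  # band -> planted templates
    montage: Montage


def make_cohort(
    n_per_group: dict[str, int] | Sequence[int],
    spec: Optional[CohortSpec] = None,
    seed: int = 0,
    duration: float = 20.0,
    sampling_rate: float = 256.0,
    n_channels: int = 52,
    snr: float = 3.0,
    bands: Optional[dict[str, BandSpec]] = None,
    dwell_mean: float = 80.0,
    dwell_shape: float = 4.0,
    amplitude: float = 15.0,
    synthesize: bool = True,
) -> Cohort:
    """Draw a cohort of subjects with group-dependent planted dynamics.

    Per subject and band, a transition matrix is drawn from the group
    mean (off-diagonal rows Dirichlet-perturbed at the configured
    concentration), a semi-Markov narrowband component is synthesized,
    and the band components are summed with one shared spatially smooth
    noise floor at the requested SNR.  Clinical scores are monotone
    functions of the designated planted transition entries plus
    Gaussian noise calibrated to the requested Spearman magnitude.

    With ``synthesize=False`` only transition matrices, state sequences
    and the clinical table are produced (no EEG rendering).
    """
    spec = spec if spec is not None else default_cohort_spec()
    bands = bands if bands is not None else BANDS
    if isinstance(n_per_group, dict):
        group_ns = dict(n_per_group)
    else:
        names = list(spec.groups)[: len(n_per_group)]
        group_ns = dict(zip(names, n_per_group))
    for g in group_ns:
        if g not in spec.groups:
            raise ValueError(f"group {g!r} has no spec")

    montage = default_montage(n_channels)
    master = np.random.SeedSequence(seed)
    template_ss, subject_root, score_ss = master.spawn(3)
    band_templates = {
        name: make_templates(montage, 4, np.random.default_rng(child))
        for name, child in zip(bands, template_ss.spawn(len(bands)))
    }

    subjects: list[tuple[str, str]] = []
    for g, n in group_ns.items():
        subjects += [(f"{g.lower()}{i + 1:02d}", g) for i in range(n)]

    recordings: list[EEGRecording] = []
    truths: dict[str, dict[str, SyntheticTruth]] = {}
    planted_rows: list[dict] = []
    for (sid, grp), child in zip(subjects, subject_root.spawn(len(subjects))):
        rng = np.random.default_rng(child)
        truths[sid] = {}
        total = None
        row: dict = {"subject_id": sid, "group": grp}
        for band_name, band in bands.items():
            eff = spec.groups[grp][band_name]
            tm = np.zeros_like(eff.mean_tp)
            for i in range(tm.shape[0]):
                off = np.flatnonzero(eff.mean_tp[i] > 0)
                alpha = eff.concentration[i] * eff.mean_tp[i, off]
                tm[i, off] = rng.dirichlet(alpha)
            cfg = SyntheticConfig(
                n_channels=n_channels,
                sampling_rate=sampling_rate,
                duration=duration,
                transition_matrix=tm,
                dwell_mean=dwell_mean,
                dwell_shape=dwell_shape,
                band=(band.low, band.high),
                snr=snr,
                amplitude=amplitude,
            )
            labels, segments = sample_state_sequence(cfg, rng)
            truth = SyntheticTruth(band_templates[band_name], labels, tm, segments)
            truths[sid][band_name] = truth
            for i in range(4):
                for j in range(4):
                    if i != j:
                        key = f"{band_name}_planted_TP_{STATE_NAMES[i]}-{STATE_NAMES[j]}"
                        row[key] = tm[i, j]
            if synthesize:
                env = _band_envelope(labels.size, cfg.band, sampling_rate, rng)
                comp = amplitude * env[None, :] * truth.templates[labels].T
                total = comp if total is None else total + comp
        planted_rows.append(row)
        if synthesize:
            sig_rms = np.sqrt(np.mean(total**2))
            if np.isfinite(snr):
                noise = _smooth_noise(montage, total.shape[1], 0.5, rng)
                noise *= sig_rms / (snr * np.sqrt(np.mean(noise**2)))
                total = total + noise
            recordings.append(
                EEGRecording(average_reference(total), sampling_rate, montage, subject_id=sid, group=grp)
            )

    planted = pd.DataFrame(planted_rows).set_index("subject_id")
    clinical = _emit_clinical(planted, spec, np.random.default_rng(score_ss))
    return Cohort(recordings, clinical, truths, band_templates, montage)


def _emit_clinical(planted: pd.DataFrame, spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    out = planted[["group"]].copy()
    lo_hi = planted["group"].map(spec.dhi_ranges)
    out["DHI"] = [rng.uniform(lo, hi) for lo, hi in lo_hi]
    is_patient = planted["group"].isin(spec.patient_groups)
    for coup in spec.couplings:
        key = f"{coup.band}_planted_TP_{STATE_NAMES[coup.from_state]}-{STATE_NAMES[coup.to_state]}"
        n_pat = int(is_patient.sum())
        if key in planted.columns:
            entry = planted.loc[is_patient, key].to_numpy()
            z = (entry - entry.mean()) / entry.std() if entry.std() > 0 else entry * 0.0
        else:  # coupled band not simulated: scores are pure noise
            z = np.zeros(n_pat)
        latent = coup.rho * z + np.sqrt(max(0.0, 1.0 - coup.rho**2)) * rng.standard_normal(n_pat)
        col = np.full(len(planted), np.nan)
        col[is_patient.to_numpy()] = coup.loc + coup.spread * latent
        # healthy controls get mild uncoupled values on the same scale
        hc = ~is_patient.to_numpy()
        baseline = {"VAS": (1.0, 0.7), "ABC": (92.0, 4.0)}.get(coup.scale, (coup.loc, coup.spread))
        col[hc] = baseline[0] + baseline[1] * rng.standard_normal(hc.sum())
        out[coup.scale] = col
    # keep the planted entries alongside for parameter-recovery checks
    for c in planted.columns:
        if c != "group":
            out[c] = planted[c]
    return out.reset_index()
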