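"""Synthetic cohorts with known ground-truth reliability structure.

Two generators are provided.

``generate_edge_panel`` works directly at the edge level: each edge carries a
population mean, a between-subject standard deviation ``sigma_b`` and a
within-subject (session) standard deviation ``sigma_w``, so its true
consistency ICC is ``sigma_b^2 / (sigma_b^2 + sigma_w^2)`` by construction.
This gives every downstream reliability estimator an exact
parameter-recovery target.

``generate_timeseries_cohort`` emulates the acquisition structure of a
two-day resting-state protocol: per subject, two sessions of (by default)
two 1,200-frame runs sampled at TR = 0.72 s.  Each subject owns a latent
region-by-region correlation matrix (population structure plus a seeded
subject-specific perturbation, projected back to a valid correlation
matrix); each session adds a further session-specific perturbation, which is
what makes edge reliability finite rather than limited only by sampling
error.  A shared low-frequency global component with subject-varying
amplitude is added to all regions, and motion spikes corrupt whole frames
while driving the accompanying RMS trace above the scrubbing threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy import signal as _signal
from statsmodels.stats.correlation_tools import corr_clipped

from .cohort import Cohort, SubjectData
from .connectome import EdgePanel, edge_index
from .preprocess import ParcellatedRun

__all__ = [
    "EdgePanelTruth",
    "CohortSpec",
    "CohortTruth",
    "generate_edge_panel",
    "generate_timeseries_cohort",
    "nearest_valid_correlation",
    "default_population_correlation",
]

#: additive signal-units SD of the corruption applied to spiked frames
SPIKE_SIGNAL_SD = 4.0
#: global component is low-pass filtered below this frequency (Hz)
GLOBAL_LOWPASS_HZ = 0.05


# ---------------------------------------------------------------------------
# edge-level generator
# ---------------------------------------------------------------------------

@dataclass
class EdgePanelTruth:
    """Ground truth for a subjects x edges panel pair.

    ``true_icc_e = sigma_b_e^2 / (sigma_b_e^2 + sigma_w_e^2)`` per edge.
    Scalars broadcast to all edges.
    """

    n_subjects: int
    n_edges: int
    mu_e: np.ndarray = 0.2
    sigma_b_e: np.ndarray = 0.1
    sigma_w_e: np.ndarray = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.n_edges < 1:
            raise ValueError("n_edges must be at least 1")
        for name in ("mu_e", "sigma_b_e", "sigma_w_e"):
            v = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), (self.n_edges,)
            ).copy()
            setattr(self, name, v)
        if np.any(self.sigma_b_e < 0) or np.any(self.sigma_w_e < 0):
            raise ValueError("standard deviations must be non-negative")
        if np.any((self.sigma_b_e == 0) & (self.sigma_w_e == 0)):
            raise ValueError("each edge needs sigma_b or sigma_w positive")

    @property
    def true_icc_e(self) -> np.ndarray:
        vb = self.sigma_b_e**2
        vw = self.sigma_w_e**2
        return vb / (vb + vw)

    @classmethod
    def from_true_icc(
        cls,
        true_icc: np.ndarray,
        n_subjects: int,
        total_sd: float = 0.1,
        mu: float | np.ndarray = 0.2,
        seed: int = 0,
    ) -> "EdgePanelTruth":
        """Build a truth record with a prescribed per-edge true ICC.

        ``total_sd`` fixes sqrt(sigma_b^2 + sigma_w^2), so the ICC alone
        decides the between/within split.
        """
        icc = np.atleast_1d(np.asarray(true_icc, dtype=float))
        if np.any((icc < 0) | (icc >= 1)):
            raise ValueError("true ICC values must lie in [0, 1)")
        return cls(
            n_subjects=n_subjects,
            n_edges=icc.size,
            mu_e=mu,
            sigma_b_e=total_sd * np.sqrt(icc),
            sigma_w_e=total_sd * np.sqrt(1.0 - icc),
            seed=seed,
        )


def generate_edge_panel(truth: EdgePanelTruth) -> tuple[EdgePanel, EdgePanel]:
    """Draw a session-1 / session-2 edge panel pair from the truth model.

    Value for edge e, subject i, session s is
    ``mu_e + b_{e,i} + eps_{e,i,s}`` with ``b ~ N(0, sigma_b_e^2)`` and
    ``eps ~ N(0, sigma_w_e^2)``, all independent.  Same seed, same output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed))
    shape = (truth.n_subjects, truth.n_edges)
    b = rng.standard_normal(shape) * truth.sigma_b_e
    e1 = rng.standard_normal(shape) * truth.sigma_w_e
    e2 = rng.standard_normal(shape) * truth.sigma_w_e
    v1 = truth.mu_e + b + e1
    v2 = truth.mu_e + b + e2
    # smallest region count whose upper triangle holds n_edges pairs
    n_regions = 2
    while n_regions * (n_regions - 1) // 2 < truth.n_edges:
        n_regions += 1
    eidx = edge_index(n_regions)[: truth.n_edges]
    subject_ids = [f"S{i:04d}" for i in range(truth.n_subjects)]
    return (
        EdgePanel(values=v1, edge_index=eidx, subject_ids=subject_ids),
        EdgePanel(values=v2, edge_index=eidx.copy(), subject_ids=list(subject_ids)),
    )


# ---------------------------------------------------------------------------
# correlation-matrix utilities
# ---------------------------------------------------------------------------

def _is_valid_correlation(a: np.ndarray, tol: float) -> bool:
    return (
        np.allclose(np.diag(a), 1.0, atol=1e-12)
        and float(np.linalg.eigvalsh(a).min()) >= -tol
    )


def nearest_valid_correlation(matrix: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Valid means symmetric, unit diagonal and positive semi-definite (smallest
    eigenvalue >= -tol).  Inputs that are already valid are returned
    unchanged (idempotence).  Projection iterates eigenvalue clipping with
    diagonal renormalization until the result is valid.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"input must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("input must be symmetric")
    a = 0.5 * (a + a.T)
    if _is_valid_correlation(a, tol):
        out = a.copy()
        np.fill_diagonal(out, 1.0)
        return out
    out = a
    for _ in range(50):
        out = corr_clipped(out, threshold=1e-8)
        out = 0.5 * (out + out.T)
        np.fill_diagonal(out, 1.0)
        if float(np.linalg.eigvalsh(out).min()) >= -tol:
            return out
    min_eig = float(np.linalg.eigvalsh(out).min())
    raise ValueError(
        f"projection failed: smallest eigenvalue {min_eig:.3e} < -{tol:.0e}"
    )


def default_population_correlation(n_regions: int) -> np.ndarray:
    """Deterministic population correlation matrix with a realistic spread.

    Built from a fixed-seed five-factor loading model (Sigma = B B' + D,
    rescaled to unit diagonal), which yields a broad, continuous distribution
    of edge strengths rather than a few discrete block values.  Depends only
    on ``n_regions``.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    rng = np.random.default_rng(np.random.SeedSequence(987654321))
    n_factors = 5
    loadings = rng.normal(0.0, 0.45, size=(n_regions, n_factors))
    loadings[:, 0] += 0.35  # shared weak positive background
    sigma = loadings @ loadings.T
    sigma += np.diag(rng.uniform(0.6, 1.4, size=n_regions))
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# timeseries-level generator
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of the synthetic acquisition.

    Defaults mirror a two-day, four-run resting-state protocol (two runs per
    session, 1,200 frames per run at TR 0.72 s).  Noise scales are chosen so
    that estimated edge reliability spans the poor-to-excellent range with a
    median in the fair band, comparable to large test-retest cohorts.
    """

    n_subjects: int
    pop_corr: np.ndarray = None
    n_regions: int = 40
    n_runs_per_session: int = 2
    n_timepoints_per_run: int = 1200
    tr_seconds: float = 0.72
    subject_dev_sd: float = 0.10
    session_dev_sd: float = 0.10
    global_amp_mean: float = 1.0
    global_amp_sd: float = 0.5
    spike_rate: float = 0.02
    spike_rms: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.n_runs_per_session < 1:
            raise ValueError("n_runs_per_session must be at least 1")
        if self.n_timepoints_per_run < 2:
            raise ValueError("n_timepoints_per_run must be at least 2")
        if not 0.0 <= self.spike_rate < 1.0:
            raise ValueError("spike_rate must lie in [0, 1)")
        if self.spike_rate > 0 and self.spike_rms <= 0.30:
            raise ValueError("spike_rms must exceed the 0.30 mm scrub threshold")
        if self.pop_corr is None:
            self.pop_corr = default_population_correlation(self.n_regions)
        self.pop_corr = np.asarray(self.pop_corr, dtype=float)
        if self.pop_corr.shape != (self.pop_corr.shape[0],) * 2:
            raise ValueError("pop_corr must be square")
        if not _is_valid_correlation(0.5 * (self.pop_corr + self.pop_corr.T), 1e-8):
            raise ValueError(
                "pop_corr must be symmetric, unit-diagonal, positive semi-definite"
            )
        self.n_regions = self.pop_corr.shape[0]


@dataclass
class CohortTruth:
    """Ground truth stored alongside a synthetic timeseries cohort."""

    pop_corr: np.ndarray
    edge_scale: np.ndarray  # per-edge multiplier on subject deviations (R, R)
    subject_latents: np.ndarray  # (S, R, R)
    session_latents: np.ndarray  # (S, 2, R, R)
    amplitudes: np.ndarray  # (S,) global-signal amplitude per subject
    spike_frames: dict[str, dict[int, list[np.ndarray]]] = field(default_factory=dict)

    def between_subject_edge_sd(self) -> np.ndarray:
        """Per-edge SD of the latent correlation across subjects (edge vector)."""
        r = self.pop_corr.shape[0]
        iu = np.triu_indices(r, k=1)
        return self.subject_latents[:, iu[0], iu[1]].std(axis=0, ddof=1)


def _symmetric_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    z = rng.standard_normal((n, n))
    z = (z + z.T) / np.sqrt(2.0)
    np.fill_diagonal(z, 0.0)
    return z


def _global_component(rng: np.random.Generator, n_frames: int, tr: float) -> np.ndarray:
    """Unit-SD smoothed random walk, low-pass filtered below 0.05 Hz."""
    walk = np.cumsum(rng.standard_normal(n_frames))
    nyq = 0.5 / tr
    if GLOBAL_LOWPASS_HZ < nyq and n_frames > 30:
        sos = _signal.butter(4, GLOBAL_LOWPASS_HZ, btype="low", fs=1.0 / tr,
                             output="sos")
        walk = _signal.sosfiltfilt(sos, walk)
    walk = walk - walk.mean()
    sd = walk.std()
    return walk / sd if sd > 0 else walk


def _matrix_sqrt(corr: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(corr)
    return v * np.sqrt(np.clip(w, 0.0, None))


def generate_timeseries_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort of parcellated runs with RMS traces.

    All randomness derives from ``spec.seed`` through per-subject
    substreams, so subject i's data are identical in any cohort generated
    with the same seed and parameters.
    """
    r = spec.n_regions
    region_names = [f"R{i:03d}" for i in range(r)]
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(spec.n_subjects + 1)
    cohort_rng = np.random.default_rng(streams[0])

    # heterogeneous per-edge scale on subject deviations: this is what makes
    # between-subject dispersion (hence true reliability) vary across edges.
    # The scale partly tracks the population edge strength (strong edges are
    # the more trait-like ones in real cohorts, where strength and
    # reliability correlate positively), plus an independent random part.
    iu = np.triu_indices(r, k=1)
    pop_edges = spec.pop_corr[iu]
    strength_rank = np.argsort(np.argsort(pop_edges)) / max(len(pop_edges) - 1, 1)
    noise_part = cohort_rng.uniform(0.0, 1.0, size=len(pop_edges))
    mix = 0.6 * strength_rank + 0.4 * noise_part
    scale = np.zeros((r, r))
    scale[iu] = 0.25 + 1.5 * mix
    scale = scale + scale.T

    subject_latents = np.empty((spec.n_subjects, r, r))
    session_latents = np.empty((spec.n_subjects, 2, r, r))
    amplitudes = np.empty(spec.n_subjects)
    spike_frames: dict[str, dict[int, list[np.ndarray]]] = {}
    subjects: list[SubjectData] = []

    for i in range(spec.n_subjects):
        rng = np.random.default_rng(streams[i + 1])
        sid = f"S{i:04d}"
        dev = spec.subject_dev_sd * scale * _symmetric_noise(rng, r)
        latent = nearest_valid_correlation(spec.pop_corr + dev)
        subject_latents[i] = latent
        amp = max(0.0, rng.normal(spec.global_amp_mean, spec.global_amp_sd))
        amplitudes[i] = amp
        subject = SubjectData(subject_id=sid)
        spike_frames[sid] = {}
        for s_idx, session in enumerate((1, 2)):
            sdev = spec.session_dev_sd * _symmetric_noise(rng, r)
            latent_s = nearest_valid_correlation(latent + sdev)
            session_latents[i, s_idx] = latent_s
            chol = _matrix_sqrt(latent_s)
            runs: list[ParcellatedRun] = []
            spike_frames[sid][session] = []
            for _run in range(spec.n_runs_per_session):
                t = spec.n_timepoints_per_run
                x = rng.standard_normal((t, r)) @ chol.T
                g = _global_component(rng, t, spec.tr_seconds)
                x = x + amp * g[:, None]
                spikes = rng.random(t) < spec.spike_rate
                spikes[0] = False
                n_spk = int(spikes.sum())
                if n_spk:
                    x[spikes] += rng.normal(0.0, SPIKE_SIGNAL_SD, size=(n_spk, r))
                rms = rng.uniform(0.01, 0.25, size=t)
                rms[0] = 0.0
                rms[spikes] = spec.spike_rms
                spike_frames[sid][session].append(np.flatnonzero(spikes))
                runs.append(
                    ParcellatedRun(
                        signal=x,
                        rms=rms,
                        tr_seconds=spec.tr_seconds,
                        region_names=list(region_names),
                    )
                )
            subject.sessions[session] = runs
        subjects.append(subject)

    truth = CohortTruth(
        pop_corr=spec.pop_corr.copy(),
        edge_scale=scale,
        subject_latents=subject_latents,
        session_latents=session_latents,
        amplitudes=amplitudes,
        spike_frames=spike_frames,
    )
    return Cohort(subjects=subjects, truth=truth)
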