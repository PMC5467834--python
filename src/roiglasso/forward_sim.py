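"""Synthetic multi-subject geometries, lead fields, activations and sensor data.

Generates the ingredients of a distributed EEG/MEG inverse problem at desk
scale: per-subject cortical-patch geometries partitioned into regions of
interest (ROIs), smooth (effectively low-rank) forward matrices with
cross-talk between adjacent ROIs, contiguous ground-truth activation
clusters, and noisy sensor recordings at a prescribed signal-to-noise ratio.

The anatomy is procedural rather than MRI-derived: each ROI is a rectangular
grid patch embedded in 3-D, and patches abut along a chain so neighbouring
ROIs share a border.  What matters to the inversion method — smoothness of
forward columns over the cortical sheet (low rank per ROI), cross-talk
between adjacent regions, and subject-to-subject variation in ROI size — is
reproduced explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ROI_NAMES",
    "DEFAULT_SIZE_PROFILE",
    "RoiGeometry",
    "SubjectForward",
    "SimulationTruth",
    "SensorRecordings",
    "generate_geometry",
    "generate_forward",
    "simulate_activity",
    "simulate_sensors",
    "default_timecourses",
    "simulate_dataset",
]

# 18 visual ROIs, one chain per hemisphere, ordered so that regions that are
# cortical neighbours sit next to each other (V2v and V4 are separated by
# V3v, the configuration used for the default simulations).
_HEMI_ORDER = ["V1", "V2v", "V3v", "V4", "LOC", "MT", "V3A", "V2d", "V3d"]
ROI_NAMES: tuple[str, ...] = tuple(
    f"{name}-{hemi}" for hemi in ("L", "R") for name in _HEMI_ORDER
)

# Desk-scale mean vertex counts per ROI (V1 the largest, MT the smallest),
# mirroring the relative areas of the visual ROIs at a fraction of the
# anatomical vertex counts.
_HEMI_SIZES = {
    "V1": 40, "V2v": 30, "V3v": 24, "V4": 24, "LOC": 24,
    "MT": 16, "V3A": 20, "V2d": 30, "V3d": 24,
}
DEFAULT_SIZE_PROFILE: tuple[int, ...] = tuple(
    _HEMI_SIZES[name.split("-")[0]] for name in ROI_NAMES
)

#: Default sensor count, time points and signal-to-noise variance ratio of
#: the simulation protocol.
N_SENSORS_DEFAULT = 128
T_DEFAULT = 91
SNR_DEFAULT = 0.32

#: RMS of a lead-field entry (arbitrary units).  Sets the overall scale of
#: the filtered designs; see docs/methods.md.
FIELD_SCALE_DEFAULT = 30.0


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class RoiGeometry:
    """One ROI's vertex geometry: 3-D coordinates plus a neighbour graph."""

    roi_id: int
    name: str
    vertex_coords: np.ndarray          # (p_i, 3)
    adjacency: csr_matrix              # symmetric vertex-neighbour relation

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency, directed=False)
        return n_comp == 1


@dataclass
class SubjectForward:
    """One subject's ROI-partitioned lead field with vertex geometry."""

    subject_id: int
    rois: list[RoiGeometry]
    F_blocks: list[np.ndarray]          # each (N, p_i)
    n_sensors: int

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def n_vertices(self) -> int:
        return sum(r.n_vertices for r in self.rois)

    @property
    def roi_slices(self) -> list[slice]:
        """Row slices of each ROI in the concatenated vertex ordering."""
        out, start = [], 0
        for r in self.rois:
            out.append(slice(start, start + r.n_vertices))
            start += r.n_vertices
        return out

    @property
    def F(self) -> np.ndarray:
        """Concatenated (N, p) forward matrix."""
        return np.concatenate(self.F_blocks, axis=1)

    @property
    def coords(self) -> np.ndarray:
        """Stacked (p, 3) vertex coordinates in block order."""
        return np.concatenate([r.vertex_coords for r in self.rois], axis=0)


@dataclass
class SimulationTruth:
    """Ground-truth vertex activity for one subject in one replicate."""

    beta_blocks: list[np.ndarray]       # each (p_i, T); zero outside clusters
    active: list[np.ndarray]            # per ROI, indices of active vertices
    amplitudes: dict[int, float]        # roi index -> cluster amplitude
    T: int
    snr: float | None = None
    noise_sigma: float | None = None

    @property
    def beta(self) -> np.ndarray:
        """Stacked (p, T) activity in block order."""
        return np.concatenate(self.beta_blocks, axis=0)

    @property
    def active_mask(self) -> np.ndarray:
        """Boolean (p,) mask over the stacked vertex ordering."""
        out = []
        for i, b in enumerate(self.beta_blocks):
            m = np.zeros(b.shape[0], dtype=bool)
            m[self.active[i]] = True
            out.append(m)
        return np.concatenate(out)


@dataclass
class SensorRecordings:
    """Noisy sensor data for one subject, with the noiseless decomposition."""

    subject_id: int
    Y: np.ndarray                       # (N, T) observed
    signal: np.ndarray                  # (N, T) noiseless F @ beta
    noise: np.ndarray                   # (N, T) realized sensor noise


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _patch_grid(p: int, x_offset: float, rng: np.random.Generator,
                z_jitter: float = 0.05):
    """Rectangular grid patch of ``p`` vertices starting at ``x_offset``.

    Vertices sit on an integer (x, y) grid with unit spacing; z is a gentle
    curved-sheet height plus a small subject-specific perturbation, so the
    patch lives in 3-D without affecting the in-plane neighbour structure.
    """
    n_cols = int(np.ceil(np.sqrt(p)))
    rows, cols = np.divmod(np.arange(p), n_cols)
    x = x_offset + cols.astype(float)
    y = rows.astype(float)
    z = 0.5 * np.sin(0.15 * x) + 0.3 * np.cos(0.2 * y)
    z = z + z_jitter * rng.standard_normal(p)
    coords = np.column_stack([x, y, z])

    # 4-neighbour adjacency on the (x, y) grid
    ii, jj = [], []
    for v in range(p):
        if cols[v] + 1 < n_cols and v + 1 < p:
            ii.append(v); jj.append(v + 1)
        if v + n_cols < p:
            ii.append(v); jj.append(v + n_cols)
    data = np.ones(2 * len(ii))
    adj = csr_matrix(
        (data, (np.r_[ii, jj], np.r_[jj, ii])), shape=(p, p)
    )
    return coords, adj


def generate_geometry(
    n_subjects: int,
    n_rois: int = 18,
    size_profile=None,
    jitter: float = 0.15,
    seed: int | np.random.SeedSequence = 0,
) -> list[list[RoiGeometry]]:
    """Generate per-subject ROI geometries as a chain of abutting patches.

    Per-subject vertex counts are drawn around ``size_profile`` with a
    multiplicative jitter of up to ``±jitter``, producing the
    subject-to-subject variation in ROI size that the grouping method has to
    cope with.  Consecutive ROIs in the chain share a border (the patch of
    ROI i+1 starts one grid step after ROI i ends), which is what produces
    forward cross-talk downstream.
    """
    if n_subjects < 1 or n_rois < 1:
        raise ValueError("n_subjects and n_rois must be positive")
    if size_profile is None:
        if n_rois == 18:
            size_profile = DEFAULT_SIZE_PROFILE
        else:
            size_profile = tuple([24] * n_rois)
    size_profile = np.asarray(size_profile, dtype=float)
    if size_profile.shape[0] != n_rois:
        raise ValueError("size_profile length must equal n_rois")
    if np.any(size_profile <= 0):
        raise ValueError("size_profile entries must be strictly positive")
    if not 0 <= jitter < 1:
        raise ValueError("jitter must be in [0, 1)")

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    subject_seeds = ss.spawn(n_subjects)

    names = ROI_NAMES if n_rois == 18 else tuple(
        f"ROI{i + 1}" for i in range(n_rois))

    subjects = []
    for k in range(n_subjects):
        rng = np.random.default_rng(subject_seeds[k])
        rois = []
        x_offset = 0.0
        for i in range(n_rois):
            factor = 1.0 + rng.uniform(-jitter, jitter)
            p_i = max(1, int(np.floor(size_profile[i] * factor + 0.5)))
            coords, adj = _patch_grid(p_i, x_offset, rng)
            rois.append(RoiGeometry(roi_id=i + 1, name=names[i],
                                    vertex_coords=coords, adjacency=adj))
            # next patch starts one grid step to the right: shared border
            x_offset = coords[:, 0].max() + 1.0
        subjects.append(rois)
    return subjects


# --------------------------------------------------------------------------
# forward matrices
# --------------------------------------------------------------------------

def _smooth_fields(coords: np.ndarray, rank: int,
                   rng: np.random.Generator) -> np.ndarray:
    """(p, rank) matrix of smooth low-frequency spatial fields.

    Columns are random long-wavelength cosines of the 3-D coordinates (plus
    an affine term for the first components), then orthonormalised; linear
    combinations of smooth fields stay smooth, so the QR step only
    conditions the basis.
    """
    p = coords.shape[0]
    n_raw = rank + 3
    fields = np.empty((p, n_raw))
    fields[:, 0] = 1.0
    fields[:, 1] = coords[:, 0] - coords[:, 0].mean()
    fields[:, 2] = coords[:, 1] - coords[:, 1].mean()
    for j in range(3, n_raw):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        wavelength = rng.uniform(6.0, 18.0)     # >> unit grid spacing
        phase = rng.uniform(0, 2 * np.pi)
        fields[:, j] = np.cos(2 * np.pi * coords @ direction / wavelength
                              + phase)
    q, _ = np.linalg.qr(fields)
    return q[:, :rank]


def generate_forward(
    geometry: list[RoiGeometry],
    n_sensors: int = N_SENSORS_DEFAULT,
    latent_rank: int = 5,
    noise_frac: float = 0.05,
    crosstalk: tuple[float, float] | float = (0.1, 0.8),
    crosstalk_rank: int = 2,
    field_scale: float = FIELD_SCALE_DEFAULT,
    seed: int | np.random.SeedSequence = 0,
    subject_id: int = 0,
) -> SubjectForward:
    """Build one subject's smooth, cross-talking lead field.

    Each ROI block is ``F_i = A_i S_iᵀ`` where ``S_i`` holds ``latent_rank``
    smooth spatial fields over the ROI's vertices and ``A_i`` holds sensor
    patterns, so every forward column varies smoothly across the cortical
    patch and the centred block has (numerical) rank ≤ ``latent_rank``.
    Adjacent ROIs leak into each other: for every neighbouring pair,
    ``crosstalk_rank`` of the latent sensor patterns are mixed across the
    border, which correlates the two ROIs' forward columns while leaving
    each ROI an identifiable subspace component (real visual areas are
    partially, not wholly, confusable).  The mixing weight for each pair is
    drawn uniformly from the ``crosstalk`` range (a scalar fixes it),
    independently per subject: how confusable two neighbours are depends on
    each subject's idiosyncratic anatomy, and it is exactly this
    subject-to-subject variation that lets a cohort settle disputes a
    single subject cannot.  A fraction ``noise_frac`` of Frobenius mass is
    unstructured roughness.
    """
    if latent_rank < 1:
        raise ValueError("latent_rank must be >= 1")
    if n_sensors < latent_rank:
        raise ValueError("n_sensors must be >= latent_rank")
    if not 0 <= noise_frac < 1:
        raise ValueError("noise_frac must be in [0, 1)")

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    R = len(geometry)

    base = [rng.standard_normal((n_sensors, latent_rank)) for _ in range(R)]
    n_pairs = max(R - 1, 1)
    if np.isscalar(crosstalk):
        pair_weights = np.full(n_pairs, float(crosstalk))
    else:
        lo, hi = crosstalk
        pair_weights = rng.uniform(lo, hi, size=n_pairs)
    m = min(crosstalk_rank, latent_rank)
    pair_comps = [rng.choice(latent_rank, size=m, replace=False)
                  for _ in range(n_pairs)]
    blocks = []
    for i, roi in enumerate(geometry):
        A = base[i].copy()
        if i > 0:
            c = pair_comps[i - 1]
            A[:, c] += pair_weights[i - 1] * base[i - 1][:, c]
        if i + 1 < R:
            c = pair_comps[i]
            A[:, c] += pair_weights[i] * base[i + 1][:, c]
        S = _smooth_fields(roi.vertex_coords, latent_rank, rng)
        smooth = A @ S.T
        smooth_norm = np.linalg.norm(smooth)
        if smooth_norm == 0:
            raise ValueError("degenerate smooth forward block")
        F = (1.0 - noise_frac) * smooth / smooth_norm
        if noise_frac > 0:
            rough = rng.standard_normal(smooth.shape)
            F = F + noise_frac * rough / np.linalg.norm(rough)
        target = field_scale * np.sqrt(F.size)
        blocks.append(F * (target / np.linalg.norm(F)))
    return SubjectForward(subject_id=subject_id, rois=list(geometry),
                          F_blocks=blocks, n_sensors=n_sensors)


# --------------------------------------------------------------------------
# ground-truth activity
# --------------------------------------------------------------------------

def _grow_cluster(adjacency: csr_matrix, start: int, size: int) -> np.ndarray:
    """Breadth-first contiguous cluster of ``size`` vertices from ``start``."""
    visited = {start}
    frontier = [start]
    order = [start]
    while len(order) < size and frontier:
        nxt = []
        for v in frontier:
            for u in adjacency.indices[
                    adjacency.indptr[v]:adjacency.indptr[v + 1]]:
                if u not in visited:
                    visited.add(u)
                    order.append(int(u))
                    nxt.append(int(u))
                    if len(order) >= size:
                        return np.array(sorted(order[:size]))
        frontier = nxt
    return np.array(sorted(order[:size]))


def default_timecourses(active_rois, T: int) -> dict[int, np.ndarray]:
    """One smooth unit-norm time course per active ROI.

    Half-sine waves with ROI-specific phases, active across the whole
    epoch and linearly independent for up to two active ROIs (all
    phase-shifted half-sines lie in the two-dimensional span of sin and
    cos, so with more than two active ROIs the signal's temporal rank
    stays 2).  Phases are chosen off the rational multiples of pi so no
    course hits an exact zero on the time grid.
    """
    t = np.arange(T, dtype=float)
    n = len(active_rois)
    phases = (np.linspace(0.45, 1.55, n) if n > 1
              else np.array([1.0]))
    out = {}
    for roi, phi in zip(active_rois, phases):
        w = np.sin(np.pi * t / max(T - 1, 1) + phi)
        out[roi] = w / np.linalg.norm(w)
    return out


def simulate_activity(
    geometry: list[RoiGeometry],
    active_rois,
    fraction: float = 0.3,
    amp_range=(1.0, 10.0),
    T: int = T_DEFAULT,
    timecourses: dict[int, np.ndarray] | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> SimulationTruth:
    """Contiguous uniform-amplitude clusters in the requested ROIs.

    ``active_rois`` are 0-based ROI indices or ROI names.  Each active ROI
    receives one cluster of ``round(fraction * p_i)`` vertices (minimum 1,
    round half up) grown breadth-first from a random seed vertex; every
    vertex in the cluster carries the same amplitude, drawn uniformly from
    ``amp_range``, times the ROI's unit-norm time course.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    lo, hi = amp_range
    if hi < lo:
        raise ValueError("amp_range must satisfy lo <= hi")

    name_to_idx = {r.name: i for i, r in enumerate(geometry)}
    idx = []
    for a in active_rois:
        if isinstance(a, str):
            if a not in name_to_idx:
                raise ValueError(f"unknown ROI name {a!r}")
            idx.append(name_to_idx[a])
        else:
            if not 0 <= a < len(geometry):
                raise ValueError(f"ROI index {a} out of range")
            idx.append(int(a))

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    if timecourses is None:
        timecourses = default_timecourses(idx, T)
    else:
        timecourses = {(name_to_idx[k] if isinstance(k, str) else k): v
                       for k, v in timecourses.items()}

    beta_blocks, active, amplitudes = [], [], {}
    for i, roi in enumerate(geometry):
        p_i = roi.n_vertices
        beta = np.zeros((p_i, T))
        act = np.array([], dtype=int)
        if i in idx:
            size = max(1, int(np.floor(fraction * p_i + 0.5)))
            start = int(rng.integers(p_i))
            act = _grow_cluster(roi.adjacency, start, size)
            amp = float(rng.uniform(lo, hi))
            amplitudes[i] = amp
            w = np.asarray(timecourses[i], dtype=float)
            if w.shape != (T,):
                raise ValueError("timecourse must be a length-T vector")
            beta[act] = amp * w
        beta_blocks.append(beta)
        active.append(act)
    return SimulationTruth(beta_blocks=beta_blocks, active=active,
                           amplitudes=amplitudes, T=T)


# --------------------------------------------------------------------------
# sensor data
# --------------------------------------------------------------------------

def simulate_sensors(
    forward: SubjectForward,
    truth: SimulationTruth,
    snr: float | None = SNR_DEFAULT,
    seed: int | np.random.SeedSequence = 0,
) -> SensorRecordings:
    """Noisy sensor recordings ``Y = Σ_i F_i β_i + ε``.

    ``snr`` is Var(noiseless signal entries) / Var(noise); the noise
    standard deviation is set so the empirical ratio matches.  ``snr=None``
    (or ``inf``) gives the noiseless record.
    """
    signal = sum(F @ b for F, b in zip(forward.F_blocks, truth.beta_blocks))
    signal = np.asarray(signal)
    if snr is None or np.isinf(snr):
        noise = np.zeros_like(signal)
        truth.noise_sigma = 0.0
        truth.snr = np.inf
        return SensorRecordings(forward.subject_id, signal.copy(),
                                signal, noise)
    if snr <= 0:
        raise ValueError("snr must be positive")
    var_sig = float(np.var(signal))
    if var_sig == 0:
        raise ValueError("zero-variance signal: sigma undefined for "
                         "finite snr")
    sigma = np.sqrt(var_sig / snr)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    noise = sigma * rng.standard_normal(signal.shape)
    truth.noise_sigma = sigma
    truth.snr = snr
    return SensorRecordings(forward.subject_id, signal + noise,
                            signal, noise)


# --------------------------------------------------------------------------
# one-call dataset
# --------------------------------------------------------------------------

def simulate_dataset(
    n_subjects: int,
    n_rois: int = 18,
    size_profile=None,
    n_sensors: int = N_SENSORS_DEFAULT,
    T: int = T_DEFAULT,
    active_rois=("V2v-L", "V4-L"),
    fraction: float = 0.3,
    amp_range=(1.0, 10.0),
    snr: float | None = SNR_DEFAULT,
    latent_rank: int = 5,
    noise_frac: float = 0.05,
    jitter: float = 0.15,
    seed: int | np.random.SeedSequence = 0,
):
    """Simulate a full multi-subject replicate of the study protocol.

    Returns ``(forwards, truths, recordings)`` — three per-subject lists.
    All randomness flows from ``seed`` through a spawning scheme, so the
    same seed reproduces the dataset exactly.
    """
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    geom_seed, *subject_seeds = ss.spawn(1 + n_subjects)
    geometries = generate_geometry(n_subjects, n_rois=n_rois,
                                   size_profile=size_profile,
                                   jitter=jitter, seed=geom_seed)
    forwards, truths, recordings = [], [], []
    for k in range(n_subjects):
        fwd_seed, act_seed, noise_seed = subject_seeds[k].spawn(3)
        fwd = generate_forward(geometries[k], n_sensors=n_sensors,
                               latent_rank=latent_rank,
                               noise_frac=noise_frac, seed=fwd_seed,
                               subject_id=k)
        truth = simulate_activity(geometries[k], active_rois,
                                  fraction=fraction, amp_range=amp_range,
                                  T=T, seed=act_seed)
        rec = simulate_sensors(fwd, truth, snr=snr, seed=noise_seed)
        forwards.append(fwd)
        truths.append(truth)
        recordings.append(rec)
    return forwards, truths, recordings
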