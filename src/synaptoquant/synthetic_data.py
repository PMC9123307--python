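"""Synthetic-data generators with ground truth for every pipeline stage.

Each generator takes a parameter dataclass plus an integer seed and is
bit-reproducible for a fixed seed (all randomness flows through a single
``numpy.random.default_rng(seed)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, PlacementError

__all__ = [
    "PunctaFieldSpec",
    "TrainSimSpec",
    "MiniTrainSpec",
    "LfpSpec",
    "GroupSampleSpec",
    "TreeSpec",
    "gen_puncta_image_pair",
    "simulate_train",
    "train_closed_form",
    "simulate_mini_trace",
    "simulate_lfp",
    "gen_group_samples",
    "gen_tree",
]


# ---------------------------------------------------------------------------
# parameter dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PunctaFieldSpec:
    """Two-channel punctate image field with a planted colocalized subset."""

    image_size: tuple[int, int] = (256, 256)
    n_puncta_a: int = 50
    n_puncta_b: int = 50
    coloc_fraction: float = 0.3
    # rendered Gaussian sigma = radius/2; radius 5 keeps the >25 px area
    # gate satisfiable at the 95-intensity cutoff
    punctum_radius_px: float = 5.0
    peak_intensity: float = 200.0
    background_sd: float = 4.0
    max_center_offset_px: float = 2.0

    def __post_init__(self):
        if not (0.0 <= self.coloc_fraction <= 1.0):
            raise ParameterError("coloc_fraction must lie in [0, 1]")
        if self.n_puncta_a < 0 or self.n_puncta_b < 0:
            raise ParameterError("puncta counts must be non-negative")
        if self.punctum_radius_px <= 0:
            raise ParameterError("punctum_radius_px must be positive")
        if min(self.image_size) < 8:
            raise ParameterError("image_size too small")
        n_pairs = round(self.coloc_fraction * self.n_puncta_a)
        if n_pairs > self.n_puncta_b:
            raise ParameterError(
                "coloc_fraction * n_puncta_a exceeds n_puncta_b; "
                "not enough partner puncta"
            )


@dataclass(frozen=True)
class TrainSimSpec:
    """Depressing stimulus-train simulation (vesicle-depletion model)."""

    n0: float = 1000.0
    p_release: float = 0.3
    r_replenish: float = 300.0
    q_amp: float = 4.0
    n_pulses: int = 100
    rate_hz: float = 20.0
    noise_sd: float = 0.0
    n_sweeps: int = 15

    def __post_init__(self):
        if not (0.0 < self.p_release <= 1.0):
            raise ParameterError("p_release must lie in (0, 1]")
        if self.n_pulses < 1:
            raise ParameterError("n_pulses must be >= 1")
        if self.n0 < 0 or self.r_replenish < 0:
            raise ParameterError("pool size and replenishment must be >= 0")
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")
        if self.n_sweeps < 1:
            raise ParameterError("n_sweeps must be >= 1")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.rate_hz

    @property
    def n_ss(self) -> float:
        """Steady-state pool size r*dt/p."""
        return self.r_replenish * self.dt_s / self.p_release


@dataclass(frozen=True)
class MiniTrainSpec:
    """Poisson miniature-event trace."""

    duration_s: float = 120.0
    event_rate_hz: float = 3.0
    amp_mean: float = 20.0
    amp_sd: float = 2.0
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 4.0
    noise_sd: float = 2.0
    fs_hz: float = 10_000.0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.event_rate_hz < 0:
            raise ParameterError("event_rate_hz must be >= 0")
        if self.tau_decay_ms <= self.tau_rise_ms:
            raise ParameterError("tau_decay_ms must exceed tau_rise_ms")
        if self.fs_hz <= 0:
            raise ParameterError("fs_hz must be positive")


@dataclass(frozen=True)
class LfpSpec:
    """Band-limited field potential with embedded spike templates."""

    duration_s: float = 10.0
    fs_hz: float = 20_000.0
    components: tuple[tuple[float, float], ...] = ((6.0, 50.0),)
    spike_times_s: tuple[float, ...] = ()
    spike_amp_sd_units: float | tuple[float, ...] = 10.0
    noise_sd: float = 5.0
    artifact_sd_limit: float = 30.0

    def __post_init__(self):
        for f, _a in self.components:
            if f >= self.fs_hz / 2:
                raise ParameterError(
                    f"component frequency {f} Hz exceeds Nyquist"
                )
        for t in self.spike_times_s:
            if not (0.0 <= t <= self.duration_s):
                raise ParameterError(
                    f"spike time {t} s lies outside [0, {self.duration_s}]"
                )
        amps = self.spike_amp_sd_units
        if not np.isscalar(amps) and len(amps) != len(self.spike_times_s):
            raise ParameterError(
                "spike_amp_sd_units must be scalar or match spike_times_s"
            )


@dataclass(frozen=True)
class GroupSampleSpec:
    """Two heavy-tailed group samples with injectable outliers."""

    n1: int = 10
    n2: int = 10
    mu1: float = 0.0
    mu2: float = 0.0
    sd1: float = 1.0
    sd2: float = 1.0
    nu: float = 30.0
    n_outliers: int = 0
    outlier_sd_offset: float = 10.0

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ParameterError("group sizes must be >= 2")
        if self.nu <= 0:
            raise ParameterError("nu must be positive")
        if self.n_outliers < 0 or self.n_outliers > self.n1:
            raise ParameterError("n_outliers must lie in [0, n1]")


@dataclass(frozen=True)
class TreeSpec:
    """Random dendritic tree written as SWC."""

    n_branches: int = 5
    segment_length_um: float = 5.0
    branch_angle_deg: float = 40.0
    total_length_um: float = 600.0

    def __post_init__(self):
        if self.n_branches < 0:
            raise ParameterError("n_branches must be >= 0")
        if self.segment_length_um <= 0 or self.total_length_um <= 0:
            raise ParameterError("lengths must be positive")
        n_segments = 1 + 2 * self.n_branches
        if self.total_length_um / n_segments < 1e-6:
            raise ParameterError("total_length_um too small for topology")


# ---------------------------------------------------------------------------
# puncta image pair
# ---------------------------------------------------------------------------

def _place_separated(rng, n, shape, margin, min_sep, existing, max_tries=20_000):
    """Dart-throwing placement keeping >= min_sep from all existing centers."""
    centers = list(existing)
    placed = []
    h, w = shape
    for _ in range(n):
        for attempt in range(max_tries):
            r = rng.uniform(margin, h - 1 - margin)
            c = rng.uniform(margin, w - 1 - margin)
            if all((r - pr) ** 2 + (c - pc) ** 2 >= min_sep**2
                   for pr, pc in centers):
                centers.append((r, c))
                placed.append((r, c))
                break
        else:
            raise PlacementError(
                f"could not place punctum with min separation {min_sep} px "
                f"in a {h}x{w} image after {max_tries} tries"
            )
    return placed


def _render_puncta(shape, centers, sigma, peak):
    img = np.zeros(shape, dtype=np.float64)
    h, w = shape
    cut = 3.0 * sigma
    for (cr, cc) in centers:
        r0, r1 = max(0, int(cr - cut)), min(h, int(cr + cut) + 2)
        c0, c1 = max(0, int(cc - cut)), min(w, int(cc + cut) + 2)
        rr, cc_ = np.mgrid[r0:r1, c0:c1]
        d2 = (rr - cr) ** 2 + (cc_ - cc) ** 2
        g = peak * np.exp(-d2 / (2.0 * sigma**2))
        g[d2 > cut**2] = 0.0  # truncate at 3 sigma
        img[r0:r1, c0:c1] += g
    return img


def gen_puncta_image_pair(spec: PunctaFieldSpec, seed: int):
    """Generate a two-channel punctate image pair with planted colocalization.

    Returns ``(image_a, image_b, truth)`` where truth is a dict with keys
    ``centers_a``, ``centers_b`` (lists of (row, col) floats) and ``pairs``
    (list of (index_a, index_b) planted colocalized pairs). The number of
    pairs is exactly ``round(coloc_fraction * n_puncta_a)``.

    Colocalized A-puncta are displaced by at most ``max_center_offset_px``
    from their B partner; all other centers keep >= 4 * punctum_radius_px
    from every already-placed center in either channel. Puncta are rendered
    as isotropic Gaussians (sigma = radius/2) truncated at 3 sigma.
    """
    rng = np.random.default_rng(seed)
    n_pairs = round(spec.coloc_fraction * spec.n_puncta_a)
    min_sep = 4.0 * spec.punctum_radius_px
    sigma = spec.punctum_radius_px / 2.0
    margin = max(3.0 * sigma + spec.max_center_offset_px + 1.0, min_sep / 2.0)
    h, w = spec.image_size
    if 2 * margin >= min(h, w):
        raise PlacementError("image too small for the requested separation")

    centers_b = _place_separated(
        rng, spec.n_puncta_b, spec.image_size, margin, min_sep, [])

    centers_a: list[tuple[float, float]] = []
    pairs: list[tuple[int, int]] = []
    partner_idx = rng.permutation(spec.n_puncta_b)[:n_pairs]
    for ia, ib in enumerate(partner_idx):
        br, bc = centers_b[ib]
        # uniform offset within the allowed disk
        theta = rng.uniform(0, 2 * math.pi)
        rad = spec.max_center_offset_px * math.sqrt(rng.uniform())
        ar = min(max(br + rad * math.cos(theta), 0.0), h - 1.0)
        ac = min(max(bc + rad * math.sin(theta), 0.0), w - 1.0)
        centers_a.append((ar, ac))
        pairs.append((ia, int(ib)))

    remaining = spec.n_puncta_a - n_pairs
    existing = centers_b + centers_a
    centers_a.extend(_place_separated(
        rng, remaining, spec.image_size, margin, min_sep, existing))

    img_a = _render_puncta(spec.image_size, centers_a, sigma,
                           spec.peak_intensity)
    img_b = _render_puncta(spec.image_size, centers_b, sigma,
                           spec.peak_intensity)
    if spec.background_sd > 0:
        img_a += rng.normal(0.0, spec.background_sd, spec.image_size)
        img_b += rng.normal(0.0, spec.background_sd, spec.image_size)
    np.clip(img_a, 0.0, None, out=img_a)
    np.clip(img_b, 0.0, None, out=img_b)

    truth = {
        "centers_a": centers_a,
        "centers_b": centers_b,
        "pairs": pairs,
        "coloc_fraction_planted": (n_pairs / spec.n_puncta_a
                                   if spec.n_puncta_a else 0.0),
    }
    return img_a, img_b, truth


# ---------------------------------------------------------------------------
# stimulus trains
# ---------------------------------------------------------------------------

def simulate_train(spec: TrainSimSpec, seed: int) -> np.ndarray:
    """Simulate depressing amplitude trains; returns (n_sweeps, n_pulses) pA.

    Depletion recursion with N1 = n0::

        released_k = p * N_k
        A_k        = q * released_k + noise
        N_{k+1}    = N_k - released_k + r * dt

    The pool is deliberately *not* capped at ``n0`` during the train:
    replenishment over a 5 s train is small relative to the initial pool,
    and leaving the recursion affine keeps the closed form exact.
    Sweep-to-sweep variability is i.i.d. additive Gaussian noise per pulse
    (no run-down).
    """
    rng = np.random.default_rng(seed)
    dt = spec.dt_s
    amps = np.empty(spec.n_pulses, dtype=np.float64)
    pool = spec.n0
    for k in range(spec.n_pulses):
        released = spec.p_release * pool
        amps[k] = spec.q_amp * released
        pool = pool - released + spec.r_replenish * dt
    table = np.tile(amps, (spec.n_sweeps, 1))
    if spec.noise_sd > 0:
        table = table + rng.normal(0.0, spec.noise_sd, table.shape)
    return table


def train_closed_form(spec: TrainSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless closed form of the depletion recursion.

    Returns ``(amplitudes, cumulative)`` with, for pulse k = 1..n::

        A_k = q * p * (N_ss + (n0 - N_ss) * (1 - p)^(k-1))
        C_n = q * p * n * N_ss + q * (n0 - N_ss) * (1 - (1 - p)^n)
    """
    k = np.arange(1, spec.n_pulses + 1, dtype=np.float64)
    p, q = spec.p_release, spec.q_amp
    nss = spec.n_ss
    amps = q * p * (nss + (spec.n0 - nss) * (1.0 - p) ** (k - 1))
    cum = q * p * k * nss + q * (spec.n0 - nss) * (1.0 - (1.0 - p) ** k)
    return amps, cum


# ---------------------------------------------------------------------------
# miniature events
# ---------------------------------------------------------------------------

def _biexp_kernel(tau_rise_s: float, tau_decay_s: float, fs: float):
    """Difference-of-exponentials kernel normalized to unit peak."""
    t_peak = (tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)
              * math.log(tau_decay_s / tau_rise_s))
    length = int(round((t_peak + 8.0 * tau_decay_s) * fs)) + 1
    t = np.arange(length) / fs
    k = np.exp(-t / tau_decay_s) - np.exp(-t / tau_rise_s)
    return k / k.max()


def simulate_mini_trace(spec: MiniTrainSpec, seed: int):
    """Simulate a miniature-PSC trace (negative-going events).

    Event times follow a homogeneous Poisson process on [0, duration];
    amplitudes are Gaussian (``amp_mean``, ``amp_sd``) and recorded in the
    truth table as positive peak magnitudes. Each event subtracts a
    difference-of-exponentials transient (unit peak scaled by amplitude)
    from the Gaussian-noise baseline, mimicking inward currents at -70 mV.

    Returns ``(trace, truth)`` where ``truth`` is a DataFrame with columns
    ``time_s`` (onset) and ``amplitude`` sorted by time.
    """
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(spec.event_rate_hz * spec.duration_s)
    times = np.sort(rng.uniform(0.0, spec.duration_s, n_events))
    amps = rng.normal(spec.amp_mean, spec.amp_sd, n_events)
    amps = np.abs(amps)  # amplitudes positive by convention

    n_samples = int(round(spec.duration_s * spec.fs_hz))
    trace = (rng.normal(0.0, spec.noise_sd, n_samples)
             if spec.noise_sd > 0 else np.zeros(n_samples))
    kernel = _biexp_kernel(spec.tau_rise_ms / 1e3, spec.tau_decay_ms / 1e3,
                           spec.fs_hz)
    for t0, a in zip(times, amps):
        i0 = int(round(t0 * spec.fs_hz))
        i1 = min(i0 + len(kernel), n_samples)
        trace[i0:i1] -= a * kernel[: i1 - i0]

    truth = pd.DataFrame({"time_s": times, "amplitude": amps})
    return trace, truth


# ---------------------------------------------------------------------------
# LFP with embedded spikes
# ---------------------------------------------------------------------------

def _spike_template(fs: float, width_s: float = 1.5e-4):
    """Negative-going spike template (unit negative peak).

    Sharp negative Gaussian plus a broad, shallow positive rebound whose
    areas cancel (zero mean, so the shape survives high-pass filtering);
    the rebound stays well below threshold when the trace is inverted.
    """
    broad_s = 4.0 * width_s
    half = int(round(5.0 * broad_s * fs))
    t = np.arange(-half, half + 1) / fs
    sharp = np.exp(-(t / width_s) ** 2 / 2.0)
    rebound = np.exp(-(t / broad_s) ** 2 / 2.0)
    tmpl = -sharp + (width_s / broad_s) * rebound
    return tmpl / abs(tmpl.min())  # negative peak exactly -1


def simulate_lfp(spec: LfpSpec, seed: int):
    """Simulate a wideband trace: sinusoids + noise + negative spikes.

    Spike templates are scaled so the raw-trace negative peak equals
    ``spike_amp_sd_units * noise_sd``. Returns ``(trace, truth)`` where
    truth is a DataFrame with ``time_s`` (template center, sorted),
    ``amp_sd_units`` and ``excluded`` (amplitude above the
    ``artifact_sd_limit`` exclusion level).
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_s * spec.fs_hz))
    t = np.arange(n) / spec.fs_hz
    trace = np.zeros(n)
    for f, a in spec.components:
        trace += a * np.sin(2.0 * math.pi * f * t)
    if spec.noise_sd > 0:
        trace += rng.normal(0.0, spec.noise_sd, n)

    times = np.asarray(spec.spike_times_s, dtype=np.float64)
    amps = np.broadcast_to(
        np.asarray(spec.spike_amp_sd_units, dtype=np.float64), times.shape
    ).copy()
    order = np.argsort(times, kind="stable")
    times, amps = times[order], amps[order]

    tmpl = _spike_template(spec.fs_hz)
    half = len(tmpl) // 2
    for t0, a in zip(times, amps):
        center = int(round(t0 * spec.fs_hz))
        i0, i1 = center - half, center + half + 1
        s0, s1 = max(0, i0), min(n, i1)
        trace[s0:s1] += (a * spec.noise_sd) * tmpl[s0 - i0: s1 - i0]

    truth = pd.DataFrame({
        "time_s": times,
        "amp_sd_units": amps,
        "excluded": amps > spec.artifact_sd_limit,
    })
    return trace, truth


# ---------------------------------------------------------------------------
# group samples
# ---------------------------------------------------------------------------

def gen_group_samples(spec: GroupSampleSpec, seed: int):
    """Draw two heavy-tailed group samples with optional planted outliers.

    Samples come from a scaled/shifted Student-t(nu); for nu > 2 the scale
    is corrected by sqrt((nu-2)/nu) so the marginal SD equals the requested
    ``sd``. ``n_outliers`` points of group 1 are replaced by
    ``mu1 + outlier_sd_offset * sd1`` exactly; truth records their indices.

    Returns ``(group1, group2, truth)``.
    """
    rng = np.random.default_rng(seed)
    corr = (math.sqrt((spec.nu - 2.0) / spec.nu) if spec.nu > 2.0 else 1.0)
    g1 = spec.mu1 + spec.sd1 * corr * rng.standard_t(spec.nu, spec.n1)
    g2 = spec.mu2 + spec.sd2 * corr * rng.standard_t(spec.nu, spec.n2)
    outlier_idx = np.sort(
        rng.choice(spec.n1, size=spec.n_outliers, replace=False))
    g1[outlier_idx] = spec.mu1 + spec.outlier_sd_offset * spec.sd1
    truth = {"outlier_indices": outlier_idx.tolist()}
    return g1, g2, truth


# ---------------------------------------------------------------------------
# random trees
# ---------------------------------------------------------------------------

def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of vector v about unit axis."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return (v * c + np.cross(axis, v) * s
            + axis * np.dot(axis, v) * (1.0 - c))


def _perpendicular(v: np.ndarray, rng) -> np.ndarray:
    while True:
        u = rng.normal(size=3)
        u -= np.dot(u, v) * v
        norm = np.linalg.norm(u)
        if norm > 1e-8:
            return u / norm


def gen_tree(spec: TreeSpec, seed: int) -> pd.DataFrame:
    """Generate a random rooted dendritic tree as an SWC table.

    The topology is a binary tree with exactly ``n_branches`` bifurcation
    points, hence ``1 + 2*n_branches`` straight segments, each of arc
    length ``total_length_um / (1 + 2*n_branches)`` sampled at roughly
    ``segment_length_um`` node spacing. Summed segment lengths therefore
    equal ``total_length_um`` up to floating point.

    Returns a DataFrame with SWC columns (id, type, x, y, z, radius,
    parent); ids are 1-based, the soma root has parent -1.
    """
    rng = np.random.default_rng(seed)
    n_segments = 1 + 2 * spec.n_branches
    seg_len = spec.total_length_um / n_segments
    half_angle = math.radians(spec.branch_angle_deg) / 2.0

    rows = [(1, 1, 0.0, 0.0, 0.0, 1.0, -1)]  # soma root
    next_id = 2

    def build_segment(parent_id, origin, direction):
        nonlocal next_id
        n_steps = max(1, int(round(seg_len / spec.segment_length_um)))
        step = seg_len / n_steps
        pos = np.array(origin, dtype=np.float64)
        pid = parent_id
        for _ in range(n_steps):
            pos = pos + direction * step
            rows.append((next_id, 3, pos[0], pos[1], pos[2], 0.5, pid))
            pid = next_id
            next_id += 1
        return pid, pos, direction

    trunk_dir = rng.normal(size=3)
    trunk_dir /= np.linalg.norm(trunk_dir)
    tips = [build_segment(1, (0.0, 0.0, 0.0), trunk_dir)]

    for _ in range(spec.n_branches):
        tip_id, tip_pos, tip_dir = tips.pop(int(rng.integers(len(tips))))
        axis = _perpendicular(tip_dir, rng)
        for sign in (+1.0, -1.0):
            child_dir = _rotate(tip_dir, axis, sign * half_angle)
            child_dir /= np.linalg.norm(child_dir)
            tips.append(build_segment(tip_id, tip_pos, child_dir))

    return pd.DataFrame(
        rows, columns=["id", "type", "x", "y", "z", "radius", "parent"])
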