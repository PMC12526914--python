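"""Synthetic TIRFM data with known ground truth.

Emulates the time-series colocalization assay: fluorescent centromeric DNAs
tethered sparsely on a coverslip, imaged in a 647-nm channel, with GFP-tagged
protein appearing on a growing fraction of them as incubation time advances.
Three products, each carrying its generating truth:

* two-channel field images (Gaussian-PSF spots on constant background with
  Gaussian camera noise),
* colocalization-count time series (the spot-level shortcut: binomial counts
  drawn straight from the kinetic curve, no rendering), and
* single-spot photobleach intensity traces (piecewise-constant with downward
  steps).

Defaults follow the assay design: 512×512 fields at 0.11 µm/px, the sampling
schedule 0, 5, 10, 30, 60, 90, 120, 150, 180 min, three biological
replicates, and ≥3000 DNAs pooled per timepoint (200 spots/field × 16
fields).  A ``mutant_mode`` flag reproduces the specificity control: a
centromere point mutant with zero true binding at all times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .imaging import FieldImage, CHANNEL_DNA, CHANNEL_GFP
from .kinetics import eval_assembly_curve, AssemblyTimeSeries, VALID_STEPS
from .photobleach import IntensityTrace

__all__ = [
    "KineticTruth",
    "SimConfig",
    "SimGroundTruth",
    "TraceTruth",
    "simulate_field_pair",
    "simulate_series",
    "simulate_traces",
]

#: camera read-noise SD in intensity units; spot peak amplitude is snr × this
NOISE_SD = 10.0
#: constant background level added to every pixel
BACKGROUND = 100.0

DEFAULT_TIMEPOINTS = (0.0, 5.0, 10.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)


class KineticTruth(NamedTuple):
    """Generating assembly curve: n sequential irreversible steps at rate k
    (min^-1) rising to plateau c_max."""

    n_steps: int
    k_per_min: float
    c_max: float

    def fraction_at(self, t_min: float) -> float:
        return float(eval_assembly_curve(self.n_steps, self.k_per_min, self.c_max, t_min))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated assay.

    ``dna_snr`` / ``gfp_snr`` are peak spot amplitude over background-noise
    SD.  ``registration_offset_px`` shifts the GFP channel relative to the
    DNA channel (constant offset only — exercises the colocalization radius
    without an alignment subsystem).  ``edge_margin_px`` keeps spots inside
    the analyzable region (detection discards a border strip); None picks
    ceil(3σ)+2.
    """

    seed: int
    n_dna_per_field: int = 200
    n_fields_per_timepoint: int = 16
    field_size_px: int = 512
    pixel_size_um: float = 0.11
    timepoints_min: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 3
    psf_sigma_px: float = 1.3
    dna_snr: float = 10.0
    gfp_snr: float = 8.0
    kinetic_truth: KineticTruth = KineticTruth(1, 0.1057, 0.87)
    mutant_mode: bool = False
    registration_offset_px: tuple[float, float] = (0.0, 0.0)
    min_separation_px: float | None = None  # default 4·psf_sigma_px
    edge_margin_px: float | None = None
    false_colocalization_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.field_size_px < 64:
            raise ValueError("field_size_px must be >= 64")
        tp = np.asarray(self.timepoints_min, float)
        if tp.ndim != 1 or len(tp) == 0 or np.any(np.diff(tp) <= 0) or tp[0] < 0:
            raise ValueError("timepoints_min must be strictly increasing and nonnegative")
        n, k, c = self.kinetic_truth
        if n not in VALID_STEPS or k <= 0 or not 0.0 <= c <= 1.0:
            raise ValueError(f"invalid kinetic_truth {self.kinetic_truth}")
        if min(self.dna_snr, self.gfp_snr) <= 0:
            raise ValueError("SNRs must be > 0")
        if self.psf_sigma_px <= 0 or self.pixel_size_um <= 0:
            raise ValueError("psf_sigma_px and pixel_size_um must be > 0")
        if self.n_dna_per_field * self.n_fields_per_timepoint < 1:
            raise ValueError("need at least one DNA per timepoint")
        if not 0.0 <= self.false_colocalization_rate <= 1.0:
            raise ValueError("false_colocalization_rate must be in [0, 1]")

    @property
    def separation_px(self) -> float:
        return (
            self.min_separation_px
            if self.min_separation_px is not None
            else 4.0 * self.psf_sigma_px
        )

    @property
    def margin_px(self) -> float:
        return (
            self.edge_margin_px
            if self.edge_margin_px is not None
            else math.ceil(3.0 * self.psf_sigma_px) + 2.0
        )

    @property
    def n_dna_per_timepoint(self) -> int:
        return self.n_dna_per_field * self.n_fields_per_timepoint

    def fraction_at(self, t_min: float) -> float:
        if self.mutant_mode:
            return 0.0
        return self.kinetic_truth.fraction_at(t_min)


class TraceTruth(NamedTuple):
    n_steps: int
    step_frames: tuple[int, ...]


@dataclass
class SimGroundTruth:
    """Generating truth behind a synthetic dataset.

    For field images: subpixel DNA positions and the bound state of each DNA.
    For count series: the true curve value and the realized bound fraction per
    (timepoint, replicate).  For traces: step counts and frames.
    """

    dna_positions: np.ndarray | None = None       # (n, 2) columns x, y
    bound_state: np.ndarray | None = None         # bool, aligned with positions
    true_fraction: float | dict | None = None     # curve value f(t)
    realized_fraction: float | dict | None = None # mean of bound_state
    trace_truth: list[TraceTruth] = field(default_factory=list)


def _place_spots(
    rng: np.random.Generator,
    n: int,
    size: int,
    min_sep: float,
    margin: float,
) -> np.ndarray:
    """Uniform positions with a minimum pairwise separation, by rejection.

    Raises when the requested count cannot fit at this density within a
    bounded number of retries.
    """
    lo, hi = margin, size - 1 - margin
    if hi <= lo:
        raise ValueError("edge margin leaves no room for spots")
    pts = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 200 * max(n, 1)
    min_sep2 = min_sep * min_sep
    while placed < n:
        if attempts >= max_attempts:
            area = (hi - lo) ** 2
            raise ValueError(
                f"could not place {n} spots with min separation {min_sep:.2f} px "
                f"in a {size}x{size} field ({placed} placed; density limit "
                f"~{area / (math.pi * min_sep2):.0f} spots)"
            )
        cand = rng.uniform(lo, hi, size=2)
        if placed:
            d2 = np.sum((pts[:placed] - cand) ** 2, axis=1)
            if d2.min() < min_sep2:
                attempts += 1
                continue
        pts[placed] = cand
        placed += 1
        attempts += 1
    return pts


def render_field(
    positions: np.ndarray,
    size: int,
    psf_sigma_px: float,
    amplitude: float,
    rng: np.random.Generator,
    background: float = BACKGROUND,
    noise_sd: float = NOISE_SD,
) -> np.ndarray:
    """Sum of symmetric 2D Gaussian spots on a constant background plus
    Gaussian read noise.  Each spot is rendered in a ±6σ window."""
    img = np.full((size, size), background, dtype=float)
    half = int(math.ceil(6.0 * psf_sigma_px))
    two_s2 = 2.0 * psf_sigma_px**2
    for x, y in np.atleast_2d(positions) if len(positions) else []:
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - half, 0), min(cx + half + 1, size)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, size)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - x
        ys = np.arange(y0, y1) - y
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / two_s2)
        img[y0:y1, x0:x1] += amplitude * g
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return img


def simulate_field_pair(
    config: SimConfig,
    t: float,
    replicate: int = 0,
    seed: int | None = None,
) -> tuple[FieldImage, FieldImage, SimGroundTruth]:
    """One two-channel field at incubation time ``t`` (minutes).

    DNA spots are placed uniformly with minimum separation (sparse
    tethering); each DNA is independently GFP-bound with probability f(t)
    from the generating curve (zero in mutant mode).  The GFP channel renders
    spots only at bound DNA positions, shifted by the registration offset —
    no orphan GFP signal.  Bit-reproducible for a fixed seed.
    """
    tp = np.asarray(config.timepoints_min, float)
    if not np.any(np.isclose(tp, t)):
        raise ValueError(f"t={t} not in configured timepoints {tuple(tp)}")
    if seed is None:
        seed = int(
            np.random.SeedSequence(
                [config.seed, int(replicate), int(round(t * 1000))]
            ).generate_state(1)[0] % (2**31)
        )
    rng = np.random.default_rng(seed)
    pos = _place_spots(
        rng, config.n_dna_per_field, config.field_size_px,
        config.separation_px, config.margin_px,
    )
    f_t = config.fraction_at(t)
    bound = rng.random(len(pos)) < f_t
    dna_img = render_field(
        pos, config.field_size_px, config.psf_sigma_px,
        config.dna_snr * NOISE_SD, rng,
    )
    offset = np.asarray(config.registration_offset_px, float)
    gfp_pos = pos[bound] + offset
    gfp_img = render_field(
        gfp_pos, config.field_size_px, config.psf_sigma_px,
        config.gfp_snr * NOISE_SD, rng,
    )
    truth = SimGroundTruth(
        dna_positions=pos,
        bound_state=bound,
        true_fraction=f_t,
        realized_fraction=float(bound.mean()) if len(bound) else 0.0,
    )
    dna = FieldImage(dna_img, CHANNEL_DNA, pixel_size_um=config.pixel_size_um, exposure_ms=300.0)
    gfp = FieldImage(gfp_img, CHANNEL_GFP, pixel_size_um=config.pixel_size_um, exposure_ms=200.0)
    return dna, gfp, truth


def simulate_series(config: SimConfig) -> tuple[AssemblyTimeSeries, SimGroundTruth]:
    """Spot-level shortcut: draw colocalized counts directly.

    Per replicate and timepoint, n_colocalized ~ Binomial(N, f(t) + chance)
    with N the pooled DNA count per timepoint; no images are rendered.  An
    additive false-colocalization rate (default 0) models chance coincidence.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_dna_per_timepoint
    rows = {"time_min": [], "replicate": [], "n_dna": [], "n_colocalized": []}
    true_frac: dict[tuple[float, int], float] = {}
    realized: dict[tuple[float, int], float] = {}
    for rep in range(config.n_replicates):
        for t in config.timepoints_min:
            p = min(config.fraction_at(t) + config.false_colocalization_rate, 1.0)
            n_col = int(rng.binomial(n_total, p))
            rows["time_min"].append(float(t))
            rows["replicate"].append(rep)
            rows["n_dna"].append(n_total)
            rows["n_colocalized"].append(n_col)
            true_frac[(float(t), rep)] = p
            realized[(float(t), rep)] = n_col / n_total
    series = AssemblyTimeSeries.from_counts(
        rows["time_min"], rows["replicate"], rows["n_dna"], rows["n_colocalized"],
        protein_label="sim", condition_label="mutant" if config.mutant_mode else "wild-type",
    )
    return series, SimGroundTruth(true_fraction=true_frac, realized_fraction=realized)


def simulate_traces(
    n_traces: int,
    steps_per_trace: int,
    snr: float,
    n_frames: int = 100,
    seed: int = 0,
    step_height: float = 100.0,
    frame_interval_s: float = 0.2,
) -> tuple[list[IntensityTrace], list[TraceTruth]]:
    """Photobleach traces: piecewise-constant with equal downward steps.

    Step frames are drawn uniformly (distinct) in the interior of the trace,
    excluding the first and last 5% of frames; Gaussian noise with
    SD = step_height / snr rides on top.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    if steps_per_trace < 0:
        raise ValueError("steps_per_trace must be >= 0")
    if snr <= 0:
        raise ValueError("snr must be > 0")
    lo = max(int(math.ceil(0.05 * n_frames)), 1)
    hi = int(math.floor(0.95 * n_frames))
    if steps_per_trace > hi - lo:
        raise ValueError(
            f"{steps_per_trace} steps do not fit in the interior frames [{lo}, {hi})"
        )
    rng = np.random.default_rng(seed)
    noise_sd = step_height / snr
    traces, truths = [], []
    for i in range(n_traces):
        frames = np.sort(rng.choice(np.arange(lo, hi), size=steps_per_trace, replace=False))
        level = np.full(n_frames, step_height * (steps_per_trace + 1), dtype=float)
        for f in frames:
            level[f:] -= step_height
        intens = level + rng.normal(0.0, noise_sd, size=n_frames)
        traces.append(
            IntensityTrace(intensities=intens, frame_interval_s=frame_interval_s,
                           spot_id=f"trace{i:04d}")
        )
        truths.append(TraceTruth(steps_per_trace, tuple(int(f) for f in frames)))
    return traces, truths


def simulate_specificity_field(
    config: SimConfig,
    seed: int,
    n_gfp: int | None = None,
) -> tuple[FieldImage, FieldImage, SimGroundTruth]:
    """Mutant-centromere-style control field: zero true binding, with GFP
    spots placed independently of the DNA spots at equal (or given) density.

    Any colocalization measured on such fields is pure spatial coincidence —
    the floor against which specific binding is judged.
    """
    rng = np.random.default_rng(seed)
    n_gfp = config.n_dna_per_field if n_gfp is None else n_gfp
    dna_pos = _place_spots(
        rng, config.n_dna_per_field, config.field_size_px,
        config.separation_px, config.margin_px,
    )
    gfp_pos = _place_spots(
        rng, n_gfp, config.field_size_px, config.separation_px, config.margin_px
    )
    dna_img = render_field(
        dna_pos, config.field_size_px, config.psf_sigma_px,
        config.dna_snr * NOISE_SD, rng,
    )
    gfp_img = render_field(
        gfp_pos, config.field_size_px, config.psf_sigma_px,
        config.gfp_snr * NOISE_SD, rng,
    )
    truth = SimGroundTruth(
        dna_positions=dna_pos,
        bound_state=np.zeros(len(dna_pos), dtype=bool),
        true_fraction=0.0,
        realized_fraction=0.0,
    )
    dna = FieldImage(dna_img, CHANNEL_DNA, pixel_size_um=config.pixel_size_um, exposure_ms=300.0)
    gfp = FieldImage(gfp_img, CHANNEL_GFP, pixel_size_um=config.pixel_size_um, exposure_ms=200.0)
    return dna, gfp, truth


def mutant_config(config: SimConfig) -> SimConfig:
    """The specificity-control condition: same geometry, zero true binding."""
    return replace(config, mutant_mode=True)
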