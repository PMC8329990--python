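"""Synthetic data with exported ground truth for every analysis stage.

The generator emulates the statistical structure the analysis assumes:

- SMLM fields: diffraction-limited isotropic Gaussian spots on a noisy
  camera background (Poisson shot noise on background + signal, additive
  Gaussian read noise, constant baseline), with per-spot integer fluorophore
  counts and stepwise photobleaching (independent exponential lifetimes per
  fluorophore).
- Nanoflow event tables: side scatter rises as a power law of diameter with
  lognormal instrument noise; green fluorescence is copy number times a
  per-copy brightness; red fluorescence marks membrane-dye-labelled
  (vesicular) particles.  Bead modes generate the four-modal silica sizing
  cocktail (68/91/113/155 nm) or the 250 nm concentration standard.
- Tetraspanin-chip capture tables: per-EV marker composition (optional
  equicorrelation via a Gaussian copula), capture on a spot only when the
  matching tetraspanin is carried, isotype (IgG) capture at a nonspecific
  rate, CF647 intensity from tetraspanin content and CF555 from GFP content.

All randomness flows from a single integer seed per call; child streams are
derived deterministically per object, so identical arguments give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from evcq._errors import ConfigError, SimulationError
from evcq.smlm import ImageStack

__all__ = [
    "SimImageConfig",
    "CopyNumberDistribution",
    "simulate_reference_field",
    "simulate_ev_field",
    "simulate_bleach_traces",
    "simulate_flow_events",
    "simulate_chip_capture",
    "FOUR_MODAL_DIAMETERS_NM",
    "ChipReadouts",
]

#: Diameters (nm) of the four-modal silica bead sizing cocktail.
FOUR_MODAL_DIAMETERS_NM = (68.0, 91.0, 113.0, 155.0)

#: Diameter (nm) of the concentration-standard beads.
CONCENTRATION_BEAD_NM = 250.0

TETRASPANINS = ("CD63", "CD81", "CD9")
ISOTYPE = "IgG"


@dataclass(frozen=True)
class SimImageConfig:
    """Camera / field geometry and noise model for simulated acquisitions.

    ``pixel_size_um`` defaults to 0.108 (a 2048-px sCMOS chip spanning a
    200x200 um field at 60x); ``psf_sigma_um`` defaults to 0.15, the nominal
    diffraction sigma inflated for frame averaging and defocus so that bright
    spots exceed the 0.1 um^2 area filter.  Setting ``shot_noise=False`` and
    ``read_noise_adu=0`` yields exactly deterministic (noiseless) frames.
    """

    width_px: int
    height_px: int
    pixel_size_um: float = 0.108
    psf_sigma_um: float = 0.15
    background_adu: float = 20.0
    read_noise_adu: float = 3.0
    baseline_adu: float = 0.0
    n_frames: int = 1
    frame_interval_s: float = 1.0
    seed: int = 0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ConfigError("image dimensions must be positive integers")
        if self.pixel_size_um <= 0 or self.psf_sigma_um <= 0:
            raise ConfigError("pixel_size_um and psf_sigma_um must be > 0")
        if min(self.background_adu, self.read_noise_adu, self.baseline_adu) < 0:
            raise ConfigError("noise parameters must be non-negative")
        if self.n_frames < 1 or self.frame_interval_s <= 0:
            raise ConfigError("need n_frames >= 1 and frame_interval_s > 0")

    @property
    def field_um(self) -> tuple[float, float]:
        return (self.width_px * self.pixel_size_um, self.height_px * self.pixel_size_um)


class CopyNumberDistribution:
    """Named per-vesicle copy-number law: fixed(k), poisson(lam), lognormal.

    The lognormal accepts either underlying-normal parameters ``mu``/``sigma``
    or a target arithmetic ``mean`` and coefficient of variation ``cv``
    (converted via sigma^2 = ln(1 + cv^2), mu = ln(mean) - sigma^2/2); draws
    are rounded to the nearest integer, floored at 0.
    """

    def __init__(self, name: str, **params: float) -> None:
        name = name.lower()
        if name == "fixed":
            if "k" not in params or params["k"] < 0:
                raise ConfigError("fixed distribution requires k >= 0")
        elif name == "poisson":
            if params.get("lam", -1) < 0:
                raise ConfigError("poisson distribution requires lam >= 0")
        elif name == "lognormal":
            if "mean" in params:
                mean = params["mean"]
                cv = params.get("cv", 0.5)
                if mean <= 0 or cv <= 0:
                    raise ConfigError("lognormal mean and cv must be > 0")
                s2 = math.log1p(cv * cv)
                params = {"mu": math.log(mean) - s2 / 2, "sigma": math.sqrt(s2)}
            elif not {"mu", "sigma"} <= params.keys():
                raise ConfigError("lognormal requires (mu, sigma) or (mean, cv)")
        else:
            raise ConfigError(f"unknown copy-number distribution {name!r}")
        self.name = name
        self.params = params

    @classmethod
    def fixed(cls, k: int) -> "CopyNumberDistribution":
        return cls("fixed", k=k)

    @classmethod
    def poisson(cls, lam: float) -> "CopyNumberDistribution":
        return cls("poisson", lam=lam)

    @classmethod
    def lognormal_mean_cv(cls, mean: float, cv: float) -> "CopyNumberDistribution":
        return cls("lognormal", mean=mean, cv=cv)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.name == "fixed":
            return np.full(n, int(self.params["k"]), dtype=np.int64)
        if self.name == "poisson":
            return rng.poisson(self.params["lam"], size=n).astype(np.int64)
        draws = rng.lognormal(self.params["mu"], self.params["sigma"], size=n)
        return np.maximum(np.rint(draws), 0).astype(np.int64)


def _coerce_distribution(spec) -> CopyNumberDistribution:
    if isinstance(spec, CopyNumberDistribution):
        return spec
    if isinstance(spec, Mapping):
        d = dict(spec)
        return CopyNumberDistribution(d.pop("name"), **d)
    if isinstance(spec, (tuple, list)) and len(spec) == 2:
        return CopyNumberDistribution(spec[0], **dict(spec[1]))
    raise ConfigError(f"cannot interpret copy-number distribution spec {spec!r}")


# ---------------------------------------------------------------------------
# spot placement and rendering
# ---------------------------------------------------------------------------

def _place_spots(
    rng: np.random.Generator,
    n: int,
    config: SimImageConfig,
    min_sep_factor: float = 4.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform placement with rejection to enforce a minimum separation.

    Spots keep a margin of 4 sigma from the field edge so their mask lies
    inside the image.  Raises "field overcrowded" when the requested count is
    incompatible with the separation constraint.
    """
    w_um, h_um = config.field_um
    margin = 4.0 * config.psf_sigma_um
    min_sep = min_sep_factor * config.psf_sigma_um
    if w_um <= 2 * margin or h_um <= 2 * margin:
        raise SimulationError("field overcrowded: field smaller than the margin")
    xs = np.empty(n)
    ys = np.empty(n)
    placed = 0
    attempts = 0
    max_attempts = max(10_000, 2_000 * n)
    while placed < n:
        if attempts >= max_attempts:
            raise SimulationError(
                f"field overcrowded: placed {placed}/{n} spots with "
                f"min separation {min_sep:.3f} um"
            )
        attempts += 1
        x = rng.uniform(margin, w_um - margin)
        y = rng.uniform(margin, h_um - margin)
        if placed:
            d2 = (xs[:placed] - x) ** 2 + (ys[:placed] - y) ** 2
            if d2.min() < min_sep * min_sep:
                continue
        xs[placed] = x
        ys[placed] = y
        placed += 1
    return xs, ys


def _render_signal(
    shape: tuple[int, int],
    x_um: np.ndarray,
    y_um: np.ndarray,
    amplitudes: np.ndarray,
    config: SimImageConfig,
) -> np.ndarray:
    """Noiseless signal field: sum of isotropic Gaussians (peak = amplitude).

    Pixel centres sit at ``(index + 0.5) * pixel_size_um``; each spot is
    rendered on a local window of +-5 sigma.
    """
    h, w = shape
    psz = config.pixel_size_um
    s_px = config.psf_sigma_um / psz
    img = np.zeros(shape, dtype=np.float64)
    rad = int(math.ceil(5.0 * s_px))
    for x, y, amp in zip(x_um, y_um, amplitudes):
        if amp == 0:
            continue
        cx = x / psz - 0.5
        cy = y / psz - 0.5
        r0 = max(0, int(round(cy)) - rad)
        r1 = min(h, int(round(cy)) + rad + 1)
        c0 = max(0, int(round(cx)) - rad)
        c1 = min(w, int(round(cx)) + rad + 1)
        rows = np.arange(r0, r1)[:, None]
        cols = np.arange(c0, c1)[None, :]
        img[r0:r1, c0:c1] += amp * np.exp(
            -((rows - cy) ** 2 + (cols - cx) ** 2) / (2.0 * s_px * s_px)
        )
    return img


def _apply_camera(
    signal_frames: np.ndarray, config: SimImageConfig, rng: np.random.Generator
) -> np.ndarray:
    """Poisson(background + signal) + Gaussian read noise + baseline, >= 0."""
    expected = signal_frames + config.background_adu
    if config.shot_noise:
        frames = rng.poisson(expected).astype(np.float64)
    else:
        frames = expected.astype(np.float64)
    if config.read_noise_adu > 0:
        frames = frames + rng.normal(0.0, config.read_noise_adu, size=frames.shape)
    frames += config.baseline_adu
    return np.clip(frames, 0.0, None)


def _snap(x_um: np.ndarray, psz: float) -> np.ndarray:
    """Snap positions to the nearest pixel centre."""
    return (np.floor(x_um / psz) + 0.5) * psz


# ---------------------------------------------------------------------------
# SMLM simulations
# ---------------------------------------------------------------------------

def simulate_reference_field(
    config: SimImageConfig,
    n_molecules: int,
    unit_peak_adu: float = 100.0,
    bleach_rate_per_s: float = 0.1,
    multi_fraction: float = 0.0,
    snap_to_pixel: bool = False,
    min_sep_factor: float = 4.0,
) -> tuple[ImageStack, np.ndarray, pd.DataFrame]:
    """Reference-fluorophore field with stepwise photobleaching.

    Emulates recombinant GFP adsorbed at low surface coverage for unit
    calibration.  A ``multi_fraction`` of spots is contaminated with 2-4
    fluorophores (to be rejected downstream by step counting).  Each
    fluorophore carries an independent exponential bleach lifetime; a
    fluorophore contributes to frame ``f`` while its lifetime exceeds
    ``f * frame_interval_s``.

    Returns ``(stack, true_traces, truth)`` where ``true_traces`` is the
    (n_spots, n_frames) noiseless above-background amplitude and ``truth``
    the ground-truth spot table.
    """
    if n_molecules < 1:
        raise ConfigError("n_molecules must be >= 1")
    if not 0.0 <= multi_fraction < 1.0:
        raise ConfigError("multi_fraction must be in [0, 1)")
    if unit_peak_adu <= 0 or bleach_rate_per_s < 0:
        raise ConfigError("unit_peak_adu must be > 0 and bleach rate >= 0")
    ss = np.random.SeedSequence(config.seed)
    r_place, r_copies, r_bleach, r_noise = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    xs, ys = _place_spots(r_place, n_molecules, config, min_sep_factor)
    if snap_to_pixel:
        xs = _snap(xs, config.pixel_size_um)
        ys = _snap(ys, config.pixel_size_um)
    copies = np.ones(n_molecules, dtype=np.int64)
    multi = r_copies.random(n_molecules) < multi_fraction
    copies[multi] = r_copies.integers(2, 5, size=int(multi.sum()))

    t = np.arange(config.n_frames) * config.frame_interval_s
    traces = np.zeros((n_molecules, config.n_frames))
    for i, k in enumerate(copies):
        if bleach_rate_per_s > 0:
            lifetimes = r_bleach.exponential(1.0 / bleach_rate_per_s, size=k)
        else:
            lifetimes = np.full(k, np.inf)
        surviving = (lifetimes[:, None] > t[None, :]).sum(axis=0)
        traces[i] = surviving * unit_peak_adu

    shape = (config.height_px, config.width_px)
    signal = np.empty((config.n_frames, *shape))
    for f in range(config.n_frames):
        signal[f] = _render_signal(shape, xs, ys, traces[:, f], config)
    frames = _apply_camera(signal, config, r_noise)
    stack = ImageStack(frames, config.pixel_size_um, config.frame_interval_s)
    truth = pd.DataFrame(
        {
            "spot_id": np.arange(n_molecules),
            "x_um": xs,
            "y_um": ys,
            "copy_number_true": copies,
            "unit_peak_adu_true": unit_peak_adu,
            "condition_label": "reference",
        }
    )
    return stack, traces, truth


def simulate_ev_field(
    config: SimImageConfig,
    n_vesicles: int,
    copy_number_distribution,
    unit_peak_adu: float = 100.0,
    max_density_per_10um2: float = 1.0,
    bleach_rate_per_s: float = 0.0,
    snap_to_pixel: bool = False,
    condition_label: str = "sample",
    min_sep_factor: float = 4.0,
) -> tuple[ImageStack, pd.DataFrame]:
    """EV field: one diffraction-limited Gaussian per vesicle.

    The noiseless above-background peak amplitude is exactly
    ``copy_number_true * unit_peak_adu`` (rendering linearity); vesicles with
    zero copies emit nothing but stay in the truth table.  The requested
    density may exceed ``max_density_per_10um2`` — the density QC downstream
    is expected to flag such fields, so the generator does not enforce it.
    With ``bleach_rate_per_s > 0`` each fluorophore bleaches during the
    acquisition exactly as in the reference field, which keeps the expected
    survival factor during frame averaging identical between calibration and
    sample when both are imaged under the same illumination.
    """
    if n_vesicles < 1:
        raise ConfigError("n_vesicles must be >= 1")
    if unit_peak_adu <= 0:
        raise ConfigError("unit_peak_adu must be > 0")
    dist = _coerce_distribution(copy_number_distribution)
    ss = np.random.SeedSequence(config.seed)
    r_place, r_copies, r_bleach, r_noise = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    xs, ys = _place_spots(r_place, n_vesicles, config, min_sep_factor)
    if snap_to_pixel:
        xs = _snap(xs, config.pixel_size_um)
        ys = _snap(ys, config.pixel_size_um)
    copies = dist.sample(r_copies, n_vesicles)

    shape = (config.height_px, config.width_px)
    if bleach_rate_per_s > 0:
        t = np.arange(config.n_frames) * config.frame_interval_s
        amps = np.zeros((n_vesicles, config.n_frames))
        for i, k in enumerate(copies):
            if k == 0:
                continue
            lifetimes = r_bleach.exponential(1.0 / bleach_rate_per_s, size=k)
            amps[i] = (lifetimes[:, None] > t[None, :]).sum(axis=0) * unit_peak_adu
        signal = np.empty((config.n_frames, *shape))
        for f in range(config.n_frames):
            signal[f] = _render_signal(shape, xs, ys, amps[:, f], config)
    else:
        one = _render_signal(shape, xs, ys, copies * float(unit_peak_adu), config)
        signal = np.repeat(one[None, :, :], config.n_frames, axis=0)
    frames = _apply_camera(signal, config, r_noise)
    stack = ImageStack(frames, config.pixel_size_um, config.frame_interval_s)
    truth = pd.DataFrame(
        {
            "spot_id": np.arange(n_vesicles),
            "x_um": xs,
            "y_um": ys,
            "copy_number_true": copies,
            "unit_peak_adu_true": unit_peak_adu,
            "condition_label": condition_label,
        }
    )
    return stack, truth


def simulate_bleach_traces(
    n_traces: int,
    n_steps: int,
    unit_adu: float = 100.0,
    noise_sigma_adu: float = 10.0,
    n_frames: int = 60,
    seed: int = 0,
    placement: str = "spaced",
    bleach_rate_per_frame: float = 0.1,
    min_gap_frames: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Standalone stepwise traces for benchmarking the step classifier.

    ``placement="spaced"`` draws step frames uniformly with a minimum gap (and
    a bleached tail), so every trace genuinely contains ``n_steps``
    distinguishable downward steps — two fluorophores bleaching in the same
    frame would otherwise merge into a single drop.  ``placement="exponential"``
    uses physical exponential lifetimes instead.

    Returns ``(traces, step_frames)`` with traces of shape
    ``(n_traces, n_frames)`` (background-free, Gaussian noise added).
    """
    if n_traces < 1 or n_steps < 1:
        raise ConfigError("need n_traces >= 1 and n_steps >= 1")
    if placement not in ("spaced", "exponential"):
        raise ConfigError(f"unknown placement {placement!r}")
    lo, hi = 2, n_frames - 3  # leave level frames at both ends
    if placement == "spaced" and (hi - lo) < n_steps * (min_gap_frames + 1):
        raise ConfigError("trace too short for the requested spaced steps")
    rng = np.random.default_rng(seed)
    traces = np.empty((n_traces, n_frames))
    steps = np.full((n_traces, n_steps), -1, dtype=np.int64)
    t = np.arange(n_frames)
    for i in range(n_traces):
        if placement == "spaced":
            while True:
                cand = np.sort(rng.integers(lo, hi, size=n_steps))
                if n_steps == 1 or np.diff(cand).min() >= min_gap_frames:
                    break
        else:
            cand = np.sort(
                np.ceil(rng.exponential(1.0 / bleach_rate_per_frame, size=n_steps))
            ).astype(np.int64)
            cand = np.clip(cand, 1, n_frames)
        steps[i, :] = cand
        level = (cand[None, :] > t[:, None]).sum(axis=1) * unit_adu
        traces[i] = level
    if noise_sigma_adu > 0:
        traces += rng.normal(0.0, noise_sigma_adu, size=traces.shape)
    return traces, steps


# ---------------------------------------------------------------------------
# nanoflow cytometry simulation
# ---------------------------------------------------------------------------

def _ssc_from_diameter(
    d_nm: np.ndarray,
    rng: np.random.Generator,
    scale_adu: float,
    exponent: float,
    noise_cv: float,
) -> np.ndarray:
    """SSC = scale * (d/100)^exponent with lognormal multiplicative noise."""
    base = scale_adu * (d_nm / 100.0) ** exponent
    if noise_cv > 0:
        s = math.sqrt(math.log1p(noise_cv * noise_cv))
        base = base * rng.lognormal(-s * s / 2, s, size=base.shape)
    return base


def simulate_flow_events(
    n_events: int,
    gfp_positive_fraction: float,
    mean_copies_positive: float = 70.0,
    purity: float = 0.9,
    bead_mode: str | None = None,
    seed: int = 0,
    diameter_mean_nm: float = 74.0,
    diameter_cv: float = 0.25,
    ssc_scale_adu: float = 1000.0,
    ssc_exponent: float = 4.0,
    ssc_noise_cv: float = 0.05,
    copy_brightness_adu: float = 1.0,
    green_bg_sigma_adu: float = 2.0,
    red_positive_adu: float = 100.0,
    red_bg_sigma_adu: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-particle nanoflow event table plus ground truth.

    EV mode (``bead_mode=None``): a ``purity`` fraction of events are
    membrane-dye-labelled vesicles with lognormal diameters (mean
    ``diameter_mean_nm``, cv ``diameter_cv``); the rest are non-vesicular
    particles (never dye-labelled, never GFP+).  A ``gfp_positive_fraction``
    of vesicles carries Poisson(``mean_copies_positive``) GFP copies; green
    fluorescence is copies x per-copy brightness plus background noise, red
    fluorescence is high iff dye-labelled.

    Bead modes: ``"four_modal"`` draws equally from the 68/91/113/155 nm
    silica cocktail; ``"concentration"`` from the 250 nm standard.  Beads are
    neither vesicles nor labelled.
    """
    if n_events < 1:
        raise ConfigError("n_events must be >= 1")
    for name, p in (("gfp_positive_fraction", gfp_positive_fraction), ("purity", purity)):
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"{name} must be in [0, 1]")
    ss = np.random.SeedSequence(seed)
    r_pop, r_size, r_ssc, r_fl = [np.random.default_rng(s) for s in ss.spawn(4)]

    if bead_mode is not None:
        if bead_mode == "four_modal":
            d = np.asarray(FOUR_MODAL_DIAMETERS_NM)[
                r_pop.integers(0, 4, size=n_events)
            ]
        elif bead_mode == "concentration":
            d = np.full(n_events, CONCENTRATION_BEAD_NM)
        else:
            raise ConfigError(f"unknown bead_mode {bead_mode!r}")
        # silica beads are tightly manufactured; ~1% size spread
        d = d * (1.0 + r_size.normal(0.0, 0.01, size=n_events))
        is_vesicle = np.zeros(n_events, dtype=bool)
        is_dye = np.zeros(n_events, dtype=bool)
        copies = np.zeros(n_events, dtype=np.int64)
    else:
        is_vesicle = r_pop.random(n_events) < purity
        is_dye = is_vesicle.copy()  # non-vesicle particles are never labelled
        s2 = math.log1p(diameter_cv * diameter_cv)
        mu = math.log(diameter_mean_nm) - s2 / 2
        d = r_size.lognormal(mu, math.sqrt(s2), size=n_events)
        # non-vesicular particles: broader, larger debris/aggregates
        n_non = int((~is_vesicle).sum())
        if n_non:
            s2n = math.log1p(0.25)
            d[~is_vesicle] = r_size.lognormal(
                math.log(100.0) - s2n / 2, math.sqrt(s2n), size=n_non
            )
        copies = np.zeros(n_events, dtype=np.int64)
        pos = is_vesicle & (r_pop.random(n_events) < gfp_positive_fraction)
        copies[pos] = r_fl.poisson(mean_copies_positive, size=int(pos.sum()))

    ssc = _ssc_from_diameter(d, r_ssc, ssc_scale_adu, ssc_exponent, ssc_noise_cv)
    green = np.clip(
        copies * copy_brightness_adu + r_fl.normal(0.0, green_bg_sigma_adu, n_events),
        0.0,
        None,
    )
    red = np.clip(
        np.where(is_dye, red_positive_adu, 0.0)
        + r_fl.normal(0.0, red_bg_sigma_adu, n_events),
        0.0,
        None,
    )
    events = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "ssc_adu": ssc,
            "fl_green_adu": green,
            "fl_red_adu": red,
        }
    )
    truth = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "diameter_nm_true": d,
            "is_vesicle": is_vesicle,
            "is_dye_labelled": is_dye,
            "gfp_copies_true": copies,
        }
    )
    return events, truth


# ---------------------------------------------------------------------------
# tetraspanin-chip capture simulation
# ---------------------------------------------------------------------------

ChipReadouts = dict  # capture antibody -> per-spot event DataFrame


def simulate_chip_capture(
    n_events: int,
    tetraspanin_frequencies: Mapping[str, float] | None = None,
    co_occurrence: float = 0.0,
    gfp_positive_fraction_by_marker: Mapping[str, float] | None = None,
    nonspecific_rate: float = 0.01,
    seed: int = 0,
    mean_gfp_copies: float = 70.0,
    cf647_per_marker_adu: float = 150.0,
    cf555_per_copy_adu: float = 1.0,
    bg_sigma_adu: float = 5.0,
    diameter_mean_nm: float = 90.0,
    diameter_cv: float = 0.35,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-capture-spot event tables for {CD63, CD81, CD9, IgG} plus truth.

    Marker composition per EV follows the given frequencies, optionally with
    equicorrelated co-occurrence (Gaussian copula, correlation
    ``co_occurrence``).  An EV is GFP+ with probability
    ``1 - prod(1 - p_m)`` over its carried markers (independent loading
    routes); positives carry Poisson(``mean_gfp_copies``) copies.  An EV is
    captured on a tetraspanin spot iff it carries that tetraspanin; the IgG
    isotype spot captures any EV at ``nonspecific_rate``.  CF647 intensity
    scales with the number of tetraspanins carried (the labelling mix targets
    all three), CF555 with the GFP copy number.
    """
    if n_events < 1:
        raise ConfigError("n_events must be >= 1")
    freqs = dict(tetraspanin_frequencies or {"CD63": 0.6, "CD81": 0.5, "CD9": 0.45})
    gfp_frac = dict(gfp_positive_fraction_by_marker or {})
    for m in TETRASPANINS:
        freqs.setdefault(m, 0.0)
        gfp_frac.setdefault(m, 0.0)
    for name, vals in (("tetraspanin_frequencies", freqs), ("gfp fractions", gfp_frac)):
        for m, p in vals.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}[{m}] = {p} outside [0, 1]")
    if not 0.0 <= nonspecific_rate <= 1.0:
        raise ConfigError("nonspecific_rate must be in [0, 1]")
    if not 0.0 <= co_occurrence < 1.0:
        raise ConfigError("co_occurrence must be in [0, 1)")

    from scipy.stats import norm

    ss = np.random.SeedSequence(seed)
    r_mark, r_gfp, r_cap, r_int = [np.random.default_rng(s) for s in ss.spawn(4)]

    if co_occurrence > 0:
        z_common = r_mark.normal(size=(n_events, 1))
        z_ind = r_mark.normal(size=(n_events, 3))
        z = math.sqrt(co_occurrence) * z_common + math.sqrt(1 - co_occurrence) * z_ind
        u = norm.cdf(z)
    else:
        u = r_mark.random((n_events, 3))
    present = np.column_stack([u[:, i] < freqs[m] for i, m in enumerate(TETRASPANINS)])

    p_miss = np.ones(n_events)
    for i, m in enumerate(TETRASPANINS):
        p_miss *= np.where(present[:, i], 1.0 - gfp_frac[m], 1.0)
    gfp_pos = r_gfp.random(n_events) < (1.0 - p_miss)
    copies = np.zeros(n_events, dtype=np.int64)
    copies[gfp_pos] = r_gfp.poisson(mean_gfp_copies, size=int(gfp_pos.sum()))

    n_markers = present.sum(axis=1)
    s2 = math.log1p(diameter_cv * diameter_cv)
    diam = r_int.lognormal(math.log(diameter_mean_nm) - s2 / 2, math.sqrt(s2), n_events)

    readouts: dict[str, pd.DataFrame] = {}
    spot_captures = {
        m: np.flatnonzero(present[:, i]) for i, m in enumerate(TETRASPANINS)
    }
    spot_captures[ISOTYPE] = np.flatnonzero(r_cap.random(n_events) < nonspecific_rate)
    for spot, idx in spot_captures.items():
        k = idx.size
        cf647 = np.clip(
            n_markers[idx] * cf647_per_marker_adu + r_int.normal(0, bg_sigma_adu, k),
            0.0,
            None,
        )
        cf555 = np.clip(
            copies[idx] * cf555_per_copy_adu + r_int.normal(0, bg_sigma_adu, k),
            0.0,
            None,
        )
        readouts[spot] = pd.DataFrame(
            {
                "event_id": idx,
                "cf647_adu": cf647,
                "cf555_adu": cf555,
                "diameter_nm": diam[idx],
            }
        )
    truth = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "cd63": present[:, 0],
            "cd81": present[:, 1],
            "cd9": present[:, 2],
            "tetraspanins_present": [
                "+".join(m for i, m in enumerate(TETRASPANINS) if present[row, i])
                for row in range(n_events)
            ],
            "gfp_copies_true": copies,
        }
    )
    return readouts, truth
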