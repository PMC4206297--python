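"""Synthetic two-channel fluorescence microscopy fields with ground truth.

Generates DAPI + target-protein (e.g. 53BP1) fields under three generative
models of the post-irradiation nuclear signal:

``unirradiated``
    Diffuse nucleoplasmic target signal at ``diffuse_mean``; no foci.
``recruitment``
    Total nuclear signal is conserved; a fraction ``r`` of it is relocated
    uniformly into focus pixels, the nucleoplasm dropping to ``(1-r)`` of its
    pre-irradiation level.
``degradation``
    Nucleoplasmic signal is multiplied by a survival fraction ``s``; focus
    pixels are *protected* and held at the pre-irradiation level.

The camera model is Poisson shot noise on (signal + background) plus additive
Gaussian read noise, quantized into a 12-bit range (0..4095).  All randomness
is driven by a single integer seed, so ``(config, seed)`` fully determines
both the field and its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import disk as _draw_disk

MAX_INTENSITY = 4095  # 12-bit camera
MODELS = ("unirradiated", "recruitment", "degradation")
PHENOTYPES = ("diffuse", "foci", "diffuse_with_foci")


class CrowdedFieldError(RuntimeError):
    """Raised when non-overlapping nucleus placement cannot terminate."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic field.

    Intensity parameters are in camera gray levels (12-bit scale); radii and
    areas are in pixels.  ``survival_fraction`` applies to the degradation
    model only, ``recruited_fraction`` to the recruitment model only.
    """

    model: str = "unirradiated"
    field_shape: tuple[int, int] = (512, 512)
    n_nuclei: int = 12
    nucleus_radius: tuple[float, float] = (14.0, 20.0)
    diffuse_mean: float = 1000.0
    nucleoli_per_nucleus: tuple[int, int] = (0, 0)
    nucleolus_radius: tuple[float, float] = (2.0, 4.0)
    foci_per_nucleus: tuple[int, int] = (5, 12)
    focus_radius: tuple[float, float] = (1.5, 2.5)
    survival_fraction: float = 0.2
    recruited_fraction: float = 0.3
    dapi_mean: float = 3000.0
    background: float = 50.0
    read_noise_sd: float = 5.0
    noise: bool = True
    seed: int = 0
    condition: Optional[str] = None

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if not (0.0 <= self.survival_fraction <= 1.0):
            raise ValueError(f"survival_fraction must be in [0,1], got {self.survival_fraction}")
        if not (0.0 <= self.recruited_fraction <= 1.0):
            raise ValueError(f"recruited_fraction must be in [0,1], got {self.recruited_fraction}")
        for name in ("nucleus_radius", "nucleolus_radius", "focus_radius"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0 or lo > hi:
                raise ValueError(f"{name} must be a positive (min, max) range, got ({lo}, {hi})")
        if self.n_nuclei < 1:
            raise ValueError("n_nuclei must be >= 1")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.diffuse_mean < 0 or self.dapi_mean < 0:
            raise ValueError("channel means must be >= 0")
        lo, hi = self.foci_per_nucleus
        if lo < 0 or lo > hi:
            raise ValueError("foci_per_nucleus must be a (min, max) count range with 0 <= min <= max")
        lo, hi = self.nucleoli_per_nucleus
        if lo < 0 or lo > hi:
            raise ValueError("nucleoli_per_nucleus must be a (min, max) count range with 0 <= min <= max")

    @property
    def label(self) -> str:
        return self.condition if self.condition is not None else self.model

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class FieldOfView:
    """Paired DAPI / target intensity grids for one acquired field."""

    dapi: np.ndarray
    target: np.ndarray
    condition: str = ""
    replicate_id: int = 0
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if self.dapi.shape != self.target.shape:
            raise ValueError(
                f"channel shape mismatch: dapi {self.dapi.shape} vs target {self.target.shape}"
            )


@dataclass
class GroundTruth:
    """Noise-free truth accompanying a simulated :class:`FieldOfView`."""

    nucleus_label_map: np.ndarray        # 0 background, k>0 per nucleus
    focus_label_map: np.ndarray          # 0 background, global focus ids
    focus_parent: dict[int, int]         # focus id -> nucleus id
    nucleolus_mask: np.ndarray           # boolean
    true_signal: np.ndarray              # expected target signal, background excluded
    per_nucleus_truth: pd.DataFrame      # one row per nucleus
    config: SimulationConfig = field(repr=False, default=None)


def apply_noise(
    true_signal: np.ndarray,
    background: float,
    read_noise_sd: float,
    seed=None,
) -> np.ndarray:
    """Camera model: Poisson(signal+background) + N(0, read_noise_sd), 12-bit clip.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    true_signal = np.asarray(true_signal, dtype=float)
    if np.any(true_signal < 0):
        raise ValueError("true_signal must be non-negative")
    if read_noise_sd < 0:
        raise ValueError("read_noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shot = rng.poisson(true_signal + background).astype(float)
    if read_noise_sd > 0:
        shot += rng.normal(0.0, read_noise_sd, size=true_signal.shape)
    return np.clip(np.rint(shot), 0, MAX_INTENSITY).astype(np.uint16)


def _quantize(expected: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(expected), 0, MAX_INTENSITY).astype(np.uint16)


def _place_nuclei(cfg: SimulationConfig, rng: np.random.Generator, max_tries: int = 2000):
    """Rejection-sample non-overlapping ellipse geometry fully inside the field.

    Overlap is forbidden conservatively via bounding circles (centre distance
    must exceed the sum of the two major semi-axes plus a 2-px gap).
    """
    h, w = cfg.field_shape
    placed = []  # (row, col, a, b, angle, rmax)
    for _ in range(cfg.n_nuclei):
        for attempt in range(max_tries):
            a = rng.uniform(*cfg.nucleus_radius)
            b = rng.uniform(*cfg.nucleus_radius)
            angle = rng.uniform(0.0, np.pi)
            rmax = max(a, b)
            margin = rmax + 2.0
            if h - margin <= margin or w - margin <= margin:
                raise CrowdedFieldError(
                    f"field {cfg.field_shape} too small for nucleus of radius {rmax:.1f}"
                )
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if all(np.hypot(r - r0, c - c0) > rmax + rm0 + 2.0 for r0, c0, _, _, _, rm0 in placed):
                placed.append((r, c, a, b, angle, rmax))
                break
        else:
            raise CrowdedFieldError(
                f"field too crowded: could not place nucleus {len(placed) + 1} of "
                f"{cfg.n_nuclei} after {max_tries} tries in field {cfg.field_shape}"
            )
    return placed


def _sample_disks_inside(
    nucleus_px: np.ndarray,
    forbidden: np.ndarray,
    n_disks: int,
    radius_range: tuple[float, float],
    shape: tuple[int, int],
    rng: np.random.Generator,
    max_tries: int = 200,
):
    """Place ``n_disks`` disks with centres in the nucleus, pixels inside the
    nucleus, avoiding ``forbidden`` pixels and each other (>=1 px separation).

    Returns a list of (rows, cols) index pairs; silently returns fewer disks
    than requested only if geometry makes placement impossible after retries.
    """
    inside = np.zeros(shape, dtype=bool)
    inside[nucleus_px] = True
    occupied = forbidden.copy()
    coords = np.flatnonzero(inside)
    out = []
    for _ in range(n_disks):
        for _try in range(max_tries):
            flat = rng.choice(coords)
            cr, cc = np.unravel_index(flat, shape)
            rad = rng.uniform(*radius_range)
            rr, cc_ = _draw_disk((cr, cc), rad, shape=shape)
            if rr.size == 0 or not inside[rr, cc_].all():
                continue
            # >=1-px separation: dilate the candidate footprint (local crop)
            r0, r1 = max(int(rr.min()) - 1, 0), min(int(rr.max()) + 2, shape[0])
            c0, c1 = max(int(cc_.min()) - 1, 0), min(int(cc_.max()) + 2, shape[1])
            crop = np.zeros((r1 - r0, c1 - c0), dtype=bool)
            crop[rr - r0, cc_ - c0] = True
            grown = ndi.binary_dilation(crop, structure=np.ones((3, 3), dtype=bool))
            if (grown & occupied[r0:r1, c0:c1]).any():
                continue
            occupied[rr, cc_] = True
            out.append((rr, cc_))
            break
    return out


def simulate_field(config: SimulationConfig) -> tuple[FieldOfView, GroundTruth]:
    """Simulate one two-channel field and its ground truth.

    Deterministic in ``(config, config.seed)``.  Raises
    :class:`CrowdedFieldError` if the requested nuclei cannot be placed.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.field_shape
    shape = (h, w)

    geometry = _place_nuclei(cfg, rng)

    nucleus_label = np.zeros(shape, dtype=np.int32)
    focus_label = np.zeros(shape, dtype=np.int32)
    nucleolus_mask = np.zeros(shape, dtype=bool)
    true_signal = np.zeros(shape, dtype=float)
    focus_parent: dict[int, int] = {}

    is_ir = cfg.model in ("recruitment", "degradation")
    rows = []
    next_focus_id = 1

    for k, (r, c, a, b, angle, _rmax) in enumerate(geometry, start=1):
        rr, cc = _draw_ellipse(r, c, a, b, shape=shape, rotation=angle)
        nucleus_label[rr, cc] = k
        nuc_px = (rr, cc)

        # nucleoli: dark holes in the target channel
        n_nucleoli = int(rng.integers(cfg.nucleoli_per_nucleus[0], cfg.nucleoli_per_nucleus[1] + 1))
        nucleoli = _sample_disks_inside(
            nuc_px, nucleolus_mask, n_nucleoli, cfg.nucleolus_radius, shape, rng
        )
        for nrr, ncc in nucleoli:
            nucleolus_mask[nrr, ncc] = True

        # foci: bright puncta, only in irradiated models
        n_foci = int(rng.integers(cfg.foci_per_nucleus[0], cfg.foci_per_nucleus[1] + 1)) if is_ir else 0
        if is_ir and cfg.model == "recruitment" and cfg.recruited_fraction > 0:
            n_foci = max(n_foci, 1)  # relocated signal needs somewhere to go
        forbidden = nucleolus_mask | (focus_label > 0)
        foci = _sample_disks_inside(nuc_px, forbidden, n_foci, cfg.focus_radius, shape, rng)
        focus_ids = []
        for frr, fcc in foci:
            focus_label[frr, fcc] = next_focus_id
            focus_parent[next_focus_id] = k
            focus_ids.append(next_focus_id)
            next_focus_id += 1

        in_nuc = nucleus_label == k
        nucleolar = in_nuc & nucleolus_mask
        focal = in_nuc & (focus_label > 0)
        nucleoplasm = in_nuc & ~nucleolar & ~focal

        area_total = int(in_nuc.sum())
        area_signal = int(area_total - nucleolar.sum())  # nucleus minus nucleoli
        area_foci = int(focal.sum())
        d = cfg.diffuse_mean

        if cfg.model == "unirradiated":
            np_val, focus_val = d, d
        elif cfg.model == "degradation":
            np_val, focus_val = cfg.survival_fraction * d, d
        else:  # recruitment: conserve d * area_signal exactly
            rfrac = cfg.recruited_fraction
            np_val = (1.0 - rfrac) * d
            if area_foci > 0:
                focus_val = np_val + rfrac * d * area_signal / area_foci
            else:
                focus_val = np_val  # rfrac == 0
        true_signal[nucleoplasm] = np_val
        true_signal[focal] = focus_val
        # nucleoli stay at 0 target signal

        rho_true = np_val / d if d > 0 else 0.0
        rows.append(
            {
                "nucleus_id": k,
                "area": area_total,
                "focus_area": area_foci,
                "focus_count": len(focus_ids),
                "nucleoplasm_mean": np_val,
                "focus_mean": focus_val if area_foci > 0 else np.nan,
                "rho_true": rho_true,
                "phenotype": _true_phenotype(len(focus_ids), rho_true),
            }
        )

    per_nucleus_truth = pd.DataFrame(rows)

    dapi_expected = np.where(nucleus_label > 0, cfg.dapi_mean, 0.0)
    if cfg.noise:
        target = apply_noise(true_signal, cfg.background, cfg.read_noise_sd, rng)
        dapi = apply_noise(dapi_expected, cfg.background, cfg.read_noise_sd, rng)
    else:
        target = _quantize(true_signal + cfg.background)
        dapi = _quantize(dapi_expected + cfg.background)

    fov = FieldOfView(dapi=dapi, target=target, condition=cfg.label, replicate_id=cfg.seed)
    truth = GroundTruth(
        nucleus_label_map=nucleus_label,
        focus_label_map=focus_label,
        focus_parent=focus_parent,
        nucleolus_mask=nucleolus_mask,
        true_signal=true_signal,
        per_nucleus_truth=per_nucleus_truth,
        config=cfg,
    )
    return fov, truth


def _true_phenotype(focus_count: int, rho: float, f_min: int = 5,
                    rho_lo: float = 0.3, rho_hi: float = 0.7) -> str:
    """Generative phenotype label, using the same decision rule the classifier
    applies to measured quantities (see :mod:`irifcyto.phenotype`)."""
    if focus_count < f_min:
        return "diffuse"
    if rho < rho_lo:
        return "foci"
    if rho >= rho_hi:
        return "diffuse_with_foci"
    return "foci" if abs(rho - rho_lo) < abs(rho - rho_hi) else "diffuse_with_foci"


def simulate_replicates(config: SimulationConfig, n_replicates: int, base_seed: int):
    """Yield ``(FieldOfView, GroundTruth)`` for seeds base_seed..base_seed+n-1."""
    for i in range(n_replicates):
        yield simulate_field(config.with_(seed=base_seed + i))
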