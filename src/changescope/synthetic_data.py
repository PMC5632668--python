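"""Synthetic stimuli, importance maps and reaction times with ground truth.

Replaces the two inputs the original experiment cannot ship: natural-image
pairs with human label maps, and human reaction times. Texture pairs are
1/f-filtered noise with programmatic manipulations whose changed-pixel mask
is known exactly; importance maps average several binary observer blob
maps; RTs come from shifted-Wald (inverse-Gaussian) channels under either a
parallel race (redundant RT = fastest channel) or a coactivation (single
accumulator, summed drifts) architecture. Every operation is deterministic
under its seed and every dataset carries its generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design_balancer import CONDITIONS, DesignAssignment, PairScore, assign_conditions, build_subsets
from .errors import InvalidParameterError
from .image_metrics import (
    ChangeRegion,
    ContrastEnergyMap,
    ImageGeometry,
    ImportanceMap,
    LuminanceImage,
    WindowSpec,
    contrast_energy_map,
    region_covariates,
    subjective_importance_change,
)
from .rt_analysis import MAX_TRIAL_S, TrialTable

MANIPULATION_MODES = ("contrast-scale", "texture-replace", "patch-delete")

__all__ = [
    "StimulusGenConfig",
    "RtGenConfig",
    "GroundTruth",
    "make_texture_image",
    "make_importance_map",
    "apply_manipulation",
    "generate_stimulus_pool",
    "simulate_rts",
    "stub_design",
]


@dataclass
class StimulusGenConfig:
    """Parameters for the image-pair pool generator."""

    seed: int
    n_pairs: int = 300
    width_px: int = 481
    height_px: int = 321
    extent_deg_x: float = 18.6
    sigma_px: float = 19.4
    spectral_slope: float = 1.0
    pairs_per_source: int = 2
    n_observers: int = 5
    blob_count_range: tuple[int, int] = (2, 4)
    blob_radius_range: tuple[float, float] = (25.0, 70.0)
    region_radius_range: tuple[float, float] = (8.0, 16.0)
    magnitude_range: tuple[float, float] = (0.15, 1.5)
    modes: tuple[str, ...] = MANIPULATION_MODES
    ecc_min_deg: float = 1.6
    decorrelation_target: float = 0.2

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise InvalidParameterError("image size must be positive")
        if self.seed is None:
            raise InvalidParameterError("seed is mandatory")

    @property
    def geometry(self) -> ImageGeometry:
        return ImageGeometry.from_extent(self.width_px, self.height_px, self.extent_deg_x)

    @property
    def window(self) -> WindowSpec:
        # sigma scales with image width so reduced-size configs stay
        # geometrically equivalent to the default 481-px layout
        return WindowSpec(sigma_px=self.sigma_px * self.width_px / 481.0)


@dataclass
class RtGenConfig:
    """Shifted-Wald channel parameters and trial-level noise settings.

    Drifts follow condition level: the low/low baseline channel is slow;
    the CE channel engages iff the pair is high-CE, the SI channel iff
    high-SI. Under ``race`` the redundant condition takes the minimum of
    the two engaged channels; under ``coactivation`` a single accumulator
    runs with the summed drifts.
    """

    seed: int
    architecture: str = "race"
    drift_baseline: float = 0.6
    drift_ce: float = 0.75
    drift_si: float = 0.75
    threshold: float = 4.0
    shift_s: float = 0.3
    n_subjects: int = 60
    subject_jitter_sd: float = 0.08
    miss_rate: float = 0.02
    false_alarm_rate: float = 0.01
    t_max_s: float = MAX_TRIAL_S

    def __post_init__(self):
        if self.architecture not in ("race", "coactivation"):
            raise InvalidParameterError(f"unknown architecture {self.architecture!r}")
        if min(self.drift_baseline, self.drift_ce, self.drift_si, self.threshold) <= 0:
            raise InvalidParameterError("drifts and threshold must be positive")
        if self.shift_s < 0:
            raise InvalidParameterError("shift must be non-negative")
        for r in (self.miss_rate, self.false_alarm_rate):
            if not 0 <= r <= 1:
                raise InvalidParameterError("rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Generating parameters stored alongside every synthetic dataset."""

    architecture: str | None = None
    condition_params: dict = field(default_factory=dict)
    pair_truth: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "condition_params": self.condition_params,
            "pair_truth": self.pair_truth,
        }


def make_texture_image(
    seed: int,
    size: tuple[int, int] = (481, 321),
    spectral_slope: float = 1.0,
    extent_deg_x: float = 18.6,
) -> LuminanceImage:
    """1/f^slope filtered-noise texture with integer luminance in [10, 250].

    Integer values make the PNG round-trip lossless, so scores recomputed
    from emitted files match the generator's ground truth exactly.
    """
    w, h = size
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # DC handled by the rescale below
    filt = 1.0 / f**spectral_slope
    filt[0, 0] = 0.0
    img = np.fft.ifft2(np.fft.fft2(white) * filt).real
    lo, hi = img.min(), img.max()
    img = 10.0 + 240.0 * (img - lo) / (hi - lo)
    return LuminanceImage(
        values=np.round(img),
        geometry=ImageGeometry.from_extent(w, h, extent_deg_x),
    )


def _ellipse_mask(shape, cx, cy, rx, ry, angle):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    u = np.cos(angle) * dx + np.sin(angle) * dy
    v = -np.sin(angle) * dx + np.cos(angle) * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_importance_map(
    seed: int,
    size: tuple[int, int] = (481, 321),
    n_observers: int = 5,
    blob_count_range: tuple[int, int] = (2, 4),
    blob_radius_range: tuple[float, float] = (25.0, 70.0),
) -> ImportanceMap:
    """Average of per-observer binary blob maps (values multiples of 1/n).

    Observers share a set of scene 'objects' but each labels a jittered
    subset, mimicking partial agreement between human annotators. The
    individual binary maps are kept on the returned object
    (``observer_maps``) for verification.
    """
    if n_observers < 1:
        raise InvalidParameterError("n_observers must be >= 1")
    w, h = size
    rng = np.random.default_rng(seed)
    n_objects = int(rng.integers(blob_count_range[0], blob_count_range[1] + 1))
    objects = [
        (
            rng.uniform(0.1 * w, 0.9 * w),
            rng.uniform(0.1 * h, 0.9 * h),
            rng.uniform(*blob_radius_range),
            rng.uniform(*blob_radius_range),
            rng.uniform(0, np.pi),
        )
        for _ in range(n_objects)
    ]
    observer_maps = []
    for _ in range(n_observers):
        m = np.zeros((h, w), dtype=bool)
        for (cx, cy, rx, ry, ang) in objects:
            if rng.random() < 0.8:  # each observer labels most objects
                jx, jy = rng.normal(0, 3, size=2)
                m |= _ellipse_mask((h, w), cx + jx, cy + jy, rx, ry, ang)
        observer_maps.append(m)
    avg = np.mean(observer_maps, axis=0)
    imap = ImportanceMap(values=avg, n_observers=n_observers)
    imap.observer_maps = observer_maps
    return imap


def _sample_region(
    rng, geom: ImageGeometry, imap, want_high_si: bool,
    radius_range, ecc_min_deg: float,
) -> ChangeRegion:
    """Elliptical change region outside the central exclusion zone.

    Centred on a labelled pixel for high-SI targets and an unlabelled pixel
    otherwise; pixels inside the exclusion radius are removed from the mask
    so no change ever touches the centre.
    """
    h, w = geom.shape
    cx0, cy0 = geom.center_px
    ecc_min_px = ecc_min_deg / geom.deg_per_px
    yy, xx = np.mgrid[0:h, 0:w]
    ecc = np.hypot(xx - cx0, yy - cy0)
    margin = radius_range[1] + 1
    in_band = (ecc >= ecc_min_px + margin) & (
        (xx >= margin) & (xx < w - margin) & (yy >= margin) & (yy < h - margin)
    )
    vals = imap.values
    cand = in_band & ((vals >= 0.6) if want_high_si else (vals <= 1e-9))
    if not cand.any():
        cand = in_band
    rows, cols = np.nonzero(cand)
    k = rng.integers(len(rows))
    cx, cy = float(cols[k]), float(rows[k])
    rx = rng.uniform(*radius_range)
    ry = rng.uniform(*radius_range)
    ang = rng.uniform(0, np.pi)
    mask = _ellipse_mask((h, w), cx, cy, rx, ry, ang)
    mask &= ecc >= ecc_min_px
    return ChangeRegion(mask=mask)


def apply_manipulation(
    img: LuminanceImage,
    mode: str,
    magnitude: float,
    region: ChangeRegion,
    seed: int = 0,
) -> tuple[LuminanceImage, ChangeRegion]:
    """Apply one programmatic change inside ``region``; returns the pair.

    Modes: ``contrast-scale`` multiplies deviations from the region mean by
    (1 + magnitude); ``texture-replace`` blends in an independent texture
    matched in mean; ``patch-delete`` blends toward the region mean (full
    deletion at magnitude 1). ``magnitude = 0`` leaves the image unchanged
    in every mode. Output luminance stays integer-valued and non-negative.
    """
    if mode not in MANIPULATION_MODES:
        raise InvalidParameterError(f"unknown manipulation mode {mode!r}")
    if region.mask.shape != img.geometry.shape:
        raise InvalidParameterError("region outside image bounds")
    out = img.values.copy()
    m = region.mask
    patch = out[m]
    mean = patch.mean()
    if mode == "contrast-scale":
        new = mean + (1.0 + magnitude) * (patch - mean)
    elif mode == "patch-delete":
        new = (1.0 - magnitude) * patch + magnitude * mean
    else:  # texture-replace
        rng = np.random.default_rng(seed)
        repl = rng.uniform(patch.min(), patch.max(), size=patch.shape)
        repl += mean - repl.mean()
        new = (1.0 - magnitude) * patch + magnitude * repl
    out[m] = np.clip(np.round(new), 0.0, None)
    return LuminanceImage(values=out, geometry=img.geometry), region


def generate_stimulus_pool(
    cfg: StimulusGenConfig, out_dir=None
) -> tuple[list[dict], list[PairScore], GroundTruth]:
    """Pool of scored image pairs spanning both median-split axes.

    The SI level is controlled by region placement (on versus off the
    labelled blobs) and the CE level by manipulation magnitude, sampled
    independently so the two change scores decorrelate (target |r| below
    ``cfg.decorrelation_target``; a warning is issued if missed). Returns a
    regeneration manifest, the scores (computed with the image-metrics
    pipeline, not copied from generation parameters) and the ground truth.
    When ``out_dir`` is given, images, maps and masks are written as PNGs.
    """
    import warnings as _warnings

    geom = cfg.geometry
    window = cfg.window
    rng = np.random.default_rng(cfg.seed)
    n_sources = -(-cfg.n_pairs // cfg.pairs_per_source)

    if out_dir is not None:
        from . import io as _io
        from pathlib import Path

        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)

    manifest, scores = [], []
    truth = GroundTruth()
    pair_idx = 0
    for s in range(n_sources):
        src_seed = int(rng.integers(2**31))
        imap_seed = int(rng.integers(2**31))
        orig = make_texture_image(
            src_seed, (cfg.width_px, cfg.height_px), cfg.spectral_slope, cfg.extent_deg_x
        )
        imap = make_importance_map(
            imap_seed, (cfg.width_px, cfg.height_px), cfg.n_observers,
            cfg.blob_count_range, cfg.blob_radius_range,
        )
        ce_orig = contrast_energy_map(orig, window)
        source_id = f"src{s:04d}"
        if out_dir is not None:
            _io.save_luminance_png(orig, out_dir / "images" / f"{source_id}_orig.png")
            _io.save_importance_png(imap, out_dir / "images" / f"{source_id}_imap.png")
        for _ in range(cfg.pairs_per_source):
            if pair_idx >= cfg.n_pairs:
                break
            pair_id = f"pair{pair_idx:04d}"
            want_high_si = bool(rng.random() < 0.5)
            mode = cfg.modes[rng.integers(len(cfg.modes))]
            magnitude = float(rng.uniform(*cfg.magnitude_range))
            manip_seed = int(rng.integers(2**31))
            region = _sample_region(
                rng, geom, imap, want_high_si, cfg.region_radius_range, cfg.ecc_min_deg
            )
            manip, region = apply_manipulation(orig, mode, magnitude, region, manip_seed)
            ce_manip = contrast_energy_map(manip, window)
            cov = region_covariates(
                orig, manip, region, window, imap=imap,
                ce_orig=ce_orig, ce_manip=ce_manip,
            )
            scores.append(
                PairScore(
                    pair_id=pair_id,
                    source_image_id=source_id,
                    ce_change=cov.ce_change,
                    si_change=cov.si_change,
                    covariates=cov.covariate_dict(),
                )
            )
            manifest.append(
                {
                    "pair_id": pair_id,
                    "source_image_id": source_id,
                    "source_seed": src_seed,
                    "imap_seed": imap_seed,
                    "manip_seed": manip_seed,
                    "mode": mode,
                    "magnitude": magnitude,
                    "want_high_si": want_high_si,
                }
            )
            truth.pair_truth[pair_id] = {
                "ce_change": cov.ce_change,
                "si_change": cov.si_change,
                "mode": mode,
                "magnitude": magnitude,
            }
            if out_dir is not None:
                _io.save_luminance_png(manip, out_dir / "images" / f"{pair_id}_manip.png")
                _io.save_mask_png(region, out_dir / "images" / f"{pair_id}_mask.png")
            pair_idx += 1

    ce = np.array([s.ce_change for s in scores])
    si = np.array([s.si_change for s in scores])
    r = float(stats.pearsonr(ce, si)[0])
    truth.condition_params["ce_si_correlation"] = r
    if abs(r) > cfg.decorrelation_target:
        _warnings.warn(
            f"ce/si correlation {r:.3f} exceeds target {cfg.decorrelation_target}; "
            "returning best-effort pool"
        )
    return manifest, scores, truth


def _wald_rts(rng, drift, threshold, n):
    """Wald first-passage times: mean a/v, shape a^2."""
    mu = threshold / drift
    lam = threshold**2
    return stats.invgauss.rvs(mu / lam, scale=lam, size=n, random_state=rng)


def _condition_channels(cond: str) -> tuple[bool, bool]:
    return cond.startswith("high"), cond.endswith("highSI")


def simulate_rts(
    design: DesignAssignment,
    cfg: RtGenConfig,
    scores: list[PairScore] | None = None,
) -> tuple[TrialTable, GroundTruth]:
    """Trial table of shifted-Wald RTs for a completed design.

    Each subject sees one subset (round-robin over subsets; all selected
    pairs if the design has none). Misses and false alarms are injected at
    the configured rates; responses slower than ``t_max_s`` are censored to
    misses. Click coordinates are not simulated (outcomes are assigned
    directly); per-trial ce/si change values are taken from ``scores`` when
    provided, otherwise synthesised consistently with the condition labels.
    """
    rng = np.random.default_rng(cfg.seed)
    a, s0 = cfg.threshold, cfg.shift_s
    truth = GroundTruth(architecture=cfg.architecture)
    for cond in CONDITIONS:
        hi_ce, hi_si = _condition_channels(cond)
        if cfg.architecture == "coactivation":
            drift = (cfg.drift_ce if hi_ce else 0.0) + (cfg.drift_si if hi_si else 0.0)
            drift = drift or cfg.drift_baseline
            truth.condition_params[cond] = {
                "mean": a / drift + s0, "shape": a**2, "shift": s0, "drift": drift,
            }
        else:
            engaged = []
            if hi_ce:
                engaged.append(cfg.drift_ce)
            if hi_si:
                engaged.append(cfg.drift_si)
            if not engaged:
                engaged = [cfg.drift_baseline]
            truth.condition_params[cond] = {
                "channel_drifts": engaged, "threshold": a, "shift": s0,
            }

    if scores is not None:
        values = {s.pair_id: (s.ce_change, s.si_change) for s in scores}
    else:
        values = {}
        for pid in design.selected:
            hi_ce, hi_si = _condition_channels(design.condition[pid])
            values[pid] = (
                float(rng.uniform(1.0, 2.0) if hi_ce else rng.uniform(0.0, 1.0)),
                float(rng.uniform(1.0, 2.0) if hi_si else rng.uniform(0.0, 1.0)),
            )

    subset_ids = sorted(design.subsets) or [None]
    frames = []
    for i in range(cfg.n_subjects):
        subject_id = f"sub{i:03d}"
        sid = subset_ids[i % len(subset_ids)]
        pairs = design.subsets[sid] if sid is not None else list(design.selected)
        a_subj = a * float(np.exp(rng.normal(0.0, cfg.subject_jitter_sd)))
        n = len(pairs)
        conds = np.array([design.condition[p] for p in pairs])
        hi_ce = np.char.startswith(conds, "high")
        hi_si = np.char.endswith(conds, "highSI")
        rt = np.empty(n)
        if cfg.architecture == "coactivation":
            drift = np.where(hi_ce, cfg.drift_ce, 0.0) + np.where(hi_si, cfg.drift_si, 0.0)
            drift[drift == 0] = cfg.drift_baseline
            for d in np.unique(drift):
                sel = drift == d
                rt[sel] = _wald_rts(rng, d, a_subj, int(sel.sum()))
        else:
            both = hi_ce & hi_si
            rt[both] = np.minimum(
                _wald_rts(rng, cfg.drift_ce, a_subj, int(both.sum())),
                _wald_rts(rng, cfg.drift_si, a_subj, int(both.sum())),
            )
            only_ce = hi_ce & ~hi_si
            rt[only_ce] = _wald_rts(rng, cfg.drift_ce, a_subj, int(only_ce.sum()))
            only_si = hi_si & ~hi_ce
            rt[only_si] = _wald_rts(rng, cfg.drift_si, a_subj, int(only_si.sum()))
            neither = ~hi_ce & ~hi_si
            rt[neither] = _wald_rts(rng, cfg.drift_baseline, a_subj, int(neither.sum()))
        rt = rt + s0
        u = rng.random(n)
        miss = (u < cfg.miss_rate) | (rt > cfg.t_max_s)
        fa = ~miss & (u < cfg.miss_rate + cfg.false_alarm_rate)
        outcome = np.where(miss, "miss", np.where(fa, "false_alarm", "hit"))
        rt[miss] = cfg.t_max_s
        ce_v = np.array([values[p][0] for p in pairs])
        si_v = np.array([values[p][1] for p in pairs])
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "pair_id": pairs,
                    "condition": conds,
                    "rt_s": rt,
                    "responded": ~miss,
                    "click_x": np.nan,
                    "click_y": np.nan,
                    "outcome": outcome,
                    "ce_change": ce_v,
                    "si_change": si_v,
                }
            )
        )
    table = TrialTable(
        pd.concat(frames, ignore_index=True),
        metadata={
            "n_subjects": cfg.n_subjects,
            "architecture": cfg.architecture,
            "subset_map": {f"sub{i:03d}": subset_ids[i % len(subset_ids)] for i in range(cfg.n_subjects)},
        },
    )
    return table, truth


def stub_design(
    n_pairs: int = 108,
    n_subsets: int = 6,
    per_subset: int = 36,
    pairs_per_source: int = 2,
    seed: int = 0,
) -> tuple[DesignAssignment, list[PairScore]]:
    """Minimal completed design without images, for RT-level simulations.

    Change scores are drawn so the median splits reproduce exactly equal
    cells; balancing covariates are independent standard normals.
    """
    if n_pairs % 4 != 0:
        raise InvalidParameterError("n_pairs must be divisible by 4")
    rng = np.random.default_rng(seed)
    per_cell = n_pairs // 4
    scores = []
    idx = 0
    for cond in CONDITIONS:
        hi_ce, hi_si = _condition_channels(cond)
        for _ in range(per_cell):
            scores.append(
                PairScore(
                    pair_id=f"pair{idx:04d}",
                    source_image_id=f"src{idx // pairs_per_source:04d}",
                    ce_change=float(rng.uniform(1.1, 2.0) if hi_ce else rng.uniform(0.1, 0.9)),
                    si_change=float(rng.uniform(1.1, 2.0) if hi_si else rng.uniform(0.1, 0.9)),
                    covariates={
                        "size_px": float(rng.normal()),
                        "eccentricity_deg": float(rng.normal()),
                        "mean_contrast": float(rng.normal()),
                        "max_contrast": float(rng.normal()),
                        "min_contrast": float(rng.normal()),
                        "luminance_change": float(rng.normal()),
                        "sf_change": float(rng.normal()),
                    },
                )
            )
            idx += 1
    rng.shuffle(scores)
    assignment = assign_conditions(scores)
    if n_subsets:
        assignment = build_subsets(assignment, n_subsets, per_subset, seed=seed)
    return assignment, scores
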