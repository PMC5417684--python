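"""Synthetic corneal OCT phantoms and synthetic subject cohorts.

Two generators make every downstream stage testable without clinical data:

* :func:`generate_bscan` builds a two-surface corneal phantom at the scanner's
  raster (1024 A-scans x 848 px by default): a circular anterior arc, a bright
  epithelial band, Generalised-Gamma-distributed stromal speckle between
  Bowman's layer and the endothelium, and low-level background noise.  The
  exact per-column boundary rows are returned as ground truth.

* :func:`generate_cohort` draws a cohort of subjects whose biometric and
  speckle-parameter marginals match configurable means/SDs (truncated to
  plausible ranges by rejection sampling) and whose measured IOP follows the
  structural model

      IOP_nc = beta_CCT * CCT + beta_GGa * GG_a + beta_0 + noise,

  with a documented linear CCT-correction stand-in producing IOP_c.

Speckle is modelled statistically, not by wave propagation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .errors import GeometryError, InsufficientDataError, ParameterDomainError
from .gg import GGParams
from .image import BScanImage

__all__ = [
    "CorneaPhantomSpec",
    "BoundaryTruth",
    "CohortSpec",
    "VariableSpec",
    "sample_gg",
    "generate_bscan",
    "generate_cohort",
    "write_bscan",
    "write_cohort",
    "COHORT_COLUMNS",
    "DEFAULT_GG_PARAMS",
]

#: Cohort-mean GG parameters used as simulation defaults.
DEFAULT_GG_PARAMS = GGParams(a=0.287, v=0.437, p=2.80)

#: Canonical cohort-table column order.
COHORT_COLUMNS = [
    "AL", "CCT", "ACD", "CR", "WTW", "IOP_c", "IOP_nc", "GG_v", "GG_a", "GG_p", "age",
]


def sample_gg(a: float, v: float, p: float, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. Generalised Gamma variates.

    Uses the exact transform X = a * G**(1/p) with G ~ Gamma(shape=v, scale=1);
    if G is gamma distributed then X is GG(a, v, p), which is the contract this
    sampler guarantees.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if not (a > 0 and v > 0 and p > 0):
        raise ParameterDomainError(f"GG parameters must be positive, got {(a, v, p)}")
    if n < 1:
        raise ParameterDomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    g = rng.gamma(shape=v, scale=1.0, size=int(n))
    return a * g ** (1.0 / p)


@dataclass(frozen=True)
class CorneaPhantomSpec:
    """Geometry and noise configuration of a synthetic corneal B-scan.

    Defaults reproduce the acquisition raster (1024 A-scans of 848 px) with a
    pixel pitch chosen so a 250 x 450 px stromal ROI fits under the anterior
    arc: 1.5 um axially and 3.5 um laterally.  ``cct_um`` and
    ``anterior_radius_mm`` are the simulation knobs for corneal thickness and
    curvature; ``epithelium_um`` is the epithelial-band thickness (anterior
    surface to Bowman's layer).
    """

    n_ascans: int = 1024
    n_axial: int = 848
    axial_pixel_um: float = 1.5
    lateral_pixel_um: float = 3.5
    anterior_radius_mm: float = 7.75
    cct_um: float = 552.75
    epithelium_um: float = 55.0
    apex_column: int = 512
    apex_row: int = 102
    background_level: float = 0.012
    epithelium_level: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.n_ascans <= 0 or self.n_axial <= 0:
            raise ParameterDomainError("raster dimensions must be positive")
        if not (self.cct_um > self.epithelium_um > 0):
            raise ParameterDomainError("require cct_um > epithelium_um > 0")
        if not (0 <= self.apex_column < self.n_ascans):
            raise ParameterDomainError("apex_column must lie inside the raster")
        if self.anterior_radius_mm <= 0:
            raise ParameterDomainError("anterior_radius_mm must be positive")
        if self.apex_row < 0:
            raise ParameterDomainError("apex_row must be non-negative")


@dataclass
class BoundaryTruth:
    """Exact per-column boundary rows of a phantom (float, 0-based)."""

    epithelium_row: np.ndarray
    bowman_row: np.ndarray
    endothelium_row: np.ndarray
    apex_column: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(self.epithelium_row.size),
                "epithelium_row": self.epithelium_row,
                "bowman_row": self.bowman_row,
                "endothelium_row": self.endothelium_row,
            }
        )


def _arc_sag_um(spec: CorneaPhantomSpec) -> np.ndarray:
    """Axial sag of the anterior circular arc below the apex, per column (um)."""
    cols = np.arange(spec.n_ascans)
    x_um = (cols - spec.apex_column) * spec.lateral_pixel_um
    r_um = spec.anterior_radius_mm * 1000.0
    if np.any(np.abs(x_um) >= r_um):
        raise GeometryError("raster wider than the anterior arc diameter")
    return r_um - np.sqrt(r_um**2 - x_um**2)


def generate_bscan(
    spec: CorneaPhantomSpec, gg: GGParams = DEFAULT_GG_PARAMS
) -> tuple[BScanImage, BoundaryTruth]:
    """Render a corneal phantom with GG stromal speckle and return ground truth.

    The anterior surface is a circular arc of ``anterior_radius_mm`` with its
    apex at (``apex_row``, ``apex_column``); Bowman's layer and the endothelium
    are parallel arcs ``epithelium_um`` and ``cct_um`` below it.  Pixels are
    drawn row-band by row-band: Rayleigh background above the surface and below
    the endothelium, a brighter Rayleigh epithelial band, and GG(a, v, p)
    speckle in the stroma, so each boundary carries a detectable axial
    gradient.  Deterministic for a fixed ``spec.seed``.
    """
    sag_um = _arc_sag_um(spec)
    ax = spec.axial_pixel_um
    epi = spec.apex_row + sag_um / ax
    bow = epi + spec.epithelium_um / ax
    endo = epi + spec.cct_um / ax
    if float(np.max(endo)) >= spec.n_axial - 1:
        raise GeometryError(
            "cornea does not fit in the raster: endothelium reaches "
            f"row {float(np.max(endo)):.0f} of {spec.n_axial}"
        )

    rng = np.random.default_rng(spec.seed)
    rows = np.arange(spec.n_axial)[:, None]
    in_epi = (rows >= np.round(epi)) & (rows < np.round(bow))
    in_stroma = (rows >= np.round(bow)) & (rows < np.round(endo))

    pixels = rng.rayleigh(scale=spec.background_level, size=(spec.n_axial, spec.n_ascans))
    n_epi = int(np.count_nonzero(in_epi))
    n_str = int(np.count_nonzero(in_stroma))
    pixels[in_epi] = rng.rayleigh(scale=spec.epithelium_level, size=n_epi)
    pixels[in_stroma] = sample_gg(gg.a, gg.v, gg.p, n_str, seed=rng)

    image = BScanImage(
        pixels=pixels,
        axial_pixel_um=spec.axial_pixel_um,
        lateral_pixel_um=spec.lateral_pixel_um,
        intensity_scale="linear",
    )
    truth = BoundaryTruth(
        epithelium_row=epi, bowman_row=bow, endothelium_row=endo,
        apex_column=spec.apex_column,
    )
    return image, truth


def write_bscan(image: BScanImage, truth: BoundaryTruth, path, scale: int = 20000):
    """Write a phantom as 16-bit grayscale TIFF/PNG plus sidecar files.

    Linear intensities are quantised as ``round(intensity * scale)`` clipped to
    the uint16 range; the factor and the pixel geometry go into a JSON sidecar
    (``<path>.json``) so readers can restore linear floats.  Ground truth is
    written to ``<stem>_truth.csv`` with 0-based rows.
    """
    import json

    import tifffile
    from PIL import Image as PILImage

    path = Path(path)
    raw = np.clip(np.round(image.pixels * scale), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raw)
    elif path.suffix.lower() == ".png":
        PILImage.fromarray(raw, mode="I;16").save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    sidecar = {
        "intensity_scale_factor": scale,
        "axial_pixel_um": image.axial_pixel_um,
        "lateral_pixel_um": image.lateral_pixel_um,
        "intensity_scale": image.intensity_scale,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    truth_path = path.with_name(path.stem + "_truth.csv")
    truth.to_frame().to_csv(truth_path, index=False)
    return path


@dataclass(frozen=True)
class VariableSpec:
    """Target mean, SD and truncation range of one cohort variable.

    ``mean`` and ``sd`` are the moments the *truncated* law should have; the
    parent normal is calibrated accordingly (see :func:`_parent_moments`).
    """

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self):
        if self.sd < 0:
            raise ParameterDomainError("SD must be non-negative")
        if not (self.lo < self.hi):
            raise ParameterDomainError("truncation range must satisfy lo < hi")


@lru_cache(maxsize=256)
def _parent_moments(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent-normal (mu0, sigma0) whose [lo, hi]-truncation has the target moments.

    Truncating N(mean, sd^2) to the observed min-max range would shrink the SD
    below its target, so the parent moments are solved for by least squares on
    the truncated-normal moment equations.  When the target SD is not
    attainable inside the range (the truncated-normal SD is bounded by the
    near-uniform limit), the closest achievable parent is used and the
    shortfall logged; the mean still matches.
    """
    from scipy import optimize as _opt
    from scipy import stats as _stats

    def resid(theta):
        mu0, log_s0 = theta
        s0 = math.exp(log_s0)
        a, b = (lo - mu0) / s0, (hi - mu0) / s0
        m = _stats.truncnorm.mean(a, b, loc=mu0, scale=s0)
        s = _stats.truncnorm.std(a, b, loc=mu0, scale=s0)
        return [(m - mean) / (hi - lo), (s - sd) / (hi - lo)]

    sol = _opt.least_squares(
        resid,
        x0=[mean, math.log(sd)],
        bounds=([lo - 5 * (hi - lo), math.log(sd) - 3], [hi + 5 * (hi - lo), math.log(sd) + 3]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    mu0, s0 = float(sol.x[0]), float(math.exp(sol.x[1]))
    achieved_sd = sd + float(sol.fun[1]) * (hi - lo)
    if abs(achieved_sd - sd) <= 1e-3 * sd:
        return mu0, s0

    # SD target unattainable inside [lo, hi]: keep the mean exact and take the
    # largest SD a truncated normal can deliver under that constraint.
    def mu_for_mean(s0):
        def mean_resid(mu0):
            a, b = (lo - mu0) / s0, (hi - mu0) / s0
            return _stats.truncnorm.mean(a, b, loc=mu0, scale=s0) - mean

        for k in (8.0, 20.0, 50.0, 200.0):
            a_, b_ = lo - k * s0, hi + k * s0
            ra, rb = mean_resid(a_), mean_resid(b_)
            if np.isfinite(ra) and np.isfinite(rb) and ra * rb < 0:
                return _opt.brentq(mean_resid, a_, b_, xtol=1e-10)
        return None  # mean not attainable at this s0

    def neg_sd(log_s0):
        s0 = math.exp(log_s0)
        mu0 = mu_for_mean(s0)
        if mu0 is None:
            return 0.0  # worst possible SD: steer the optimiser away
        a, b = (lo - mu0) / s0, (hi - mu0) / s0
        # parents with almost no mass in [lo, hi] would make rejection
        # sampling intractable; exclude them
        if _stats.norm.cdf(b) - _stats.norm.cdf(a) < 0.01:
            return 0.0
        return -_stats.truncnorm.std(a, b, loc=mu0, scale=s0)

    # coarse grid then local refinement: neg_sd has flat excluded regions
    grid = np.linspace(math.log(sd) - 3, math.log(sd) + 3, 61)
    vals = np.array([neg_sd(g) for g in grid])
    i = int(np.argmin(vals))
    left, right = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    opt = _opt.minimize_scalar(neg_sd, bounds=(left, right), method="bounded",
                               options={"xatol": 1e-8})
    s0 = float(math.exp(opt.x))
    mu0 = mu_for_mean(s0)
    if mu0 is None:  # refinement strayed into an excluded region
        s0 = float(math.exp(grid[i]))
        mu0 = mu_for_mean(s0)
    logger.warning(
        "truncated-normal SD target %.4g unattainable on [%.4g, %.4g]; "
        "using closest achievable %.4g with exact mean", sd, lo, hi, -float(opt.fun),
    )
    return float(mu0), s0


def _default_marginals() -> dict[str, VariableSpec]:
    # Cohort marginals: healthy adult biometry and corneal speckle statistics.
    return {
        "CCT": VariableSpec(552.75, 27.89, 488.0, 612.0),     # um
        "CR": VariableSpec(7.75, 0.25, 7.24, 8.50),           # mm
        "AL": VariableSpec(23.29, 0.82, 21.64, 24.88),        # mm
        "ACD": VariableSpec(3.28, 0.38, 2.58, 4.14),          # mm
        "WTW": VariableSpec(11.99, 0.32, 11.40, 12.70),       # mm
        "age": VariableSpec(44.66, 19.32, 22.0, 78.0),        # years
        "GG_a": VariableSpec(0.287, 0.035, 0.21, 0.38),       # a.u.
        "GG_v": VariableSpec(0.437, 0.029, 0.37, 0.52),       # a.u.
        "GG_p": VariableSpec(2.80, 0.27, 2.28, 3.41),         # a.u.
    }


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic tonometry cohort.

    ``iop_coefficients`` are (beta_CCT, beta_GGa, beta_0) of the structural
    model for the measured (non-corrected) IOP; the default noise SD of
    1.13 mmHg makes that model explain ~39% of the IOP variance at the default
    marginals.  ``cct_correction_slope`` is the linear CCT-correction stand-in
    (anchored at 550 um) that produces IOP_c; its default equals beta_CCT so
    the corrected pressure is CCT-independent.
    """

    n_subjects: int = 56
    marginals: dict[str, VariableSpec] = field(default_factory=_default_marginals)
    iop_coefficients: tuple[float, float, float] = (0.0248, -16.534, 6.853)
    noise_sd: float = 1.13
    cct_correction_slope: float = 0.0248
    cct_anchor_um: float = 550.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 3:
            raise InsufficientDataError("a cohort needs n_subjects >= 3")
        if self.noise_sd < 0:
            raise ParameterDomainError("noise_sd must be non-negative")


def _truncated_normal(rng, var: VariableSpec, n: int) -> np.ndarray:
    """Rejection-sample the calibrated parent normal truncated to [lo, hi]."""
    if var.sd == 0:
        return np.full(n, var.mean)
    mu0, s0 = _parent_moments(var.mean, var.sd, var.lo, var.hi)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mu0, s0, size=2 * (n - filled) + 16)
        keep = draw[(draw >= var.lo) & (draw <= var.hi)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table with the canonical column schema.

    Biometry, age and GG parameters are independent truncated normals;
    IOP_nc follows the structural model plus Gaussian noise, and IOP_c is
    IOP_nc minus the linear CCT correction.  Reproducible under ``spec.seed``.
    Returns a DataFrame with columns AL, CCT, ACD, CR, WTW, IOP_c, IOP_nc,
    GG_v, GG_a, GG_p, age (plus subject_id and the derived GG_v_over_p).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cols = {
        name: _truncated_normal(rng, var, n) for name, var in spec.marginals.items()
    }
    b_cct, b_gga, b0 = spec.iop_coefficients
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
    iop_nc = b_cct * cols["CCT"] + b_gga * cols["GG_a"] + b0 + noise
    iop_c = iop_nc - spec.cct_correction_slope * (cols["CCT"] - spec.cct_anchor_um)
    df = pd.DataFrame(cols)
    df["IOP_nc"] = iop_nc
    df["IOP_c"] = iop_c
    df["GG_v_over_p"] = df["GG_v"] / df["GG_p"]
    df.insert(0, "subject_id", np.arange(1, n + 1))
    return df[["subject_id"] + COHORT_COLUMNS + ["GG_v_over_p"]]


def write_cohort(df: pd.DataFrame, basepath) -> tuple[Path, Path]:
    """Write a cohort as CSV and XLSX with the canonical column names."""
    basepath = Path(basepath)
    out = df[COHORT_COLUMNS]
    csv_path = basepath.with_suffix(".csv")
    xlsx_path = basepath.with_suffix(".xlsx")
    out.to_csv(csv_path, index=False)
    out.to_excel(xlsx_path, index=False)
    return csv_path, xlsx_path
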