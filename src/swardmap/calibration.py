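"""Canopy-fraction to biomass-fraction calibration.

A canopy image only shows the top of the sward, while agronomic decisions
need the *biomass* species composition.  The link is calibrated on paired
samples: a 0.5 x 0.5 m quadrat is photographed, cut, hand-sorted into
grass / white clover / red clover / weeds, dried, and weighed.  The dry
weight of a sorted fraction weighing under 5 g fresh is estimated at a 25%
dry-matter content.  The calibration is a first-order linear model (OLS,
intercept included) from the canopy fraction of a species to its relative
dry-matter fraction, reported as R^2; generalization across locations is
probed by decomposing R^2 by site / seasonal cut and by leave-one-site-out
(LOSO) prediction with per-site mean absolute error in percentage points.

A synthetic pair generator emulates the statistical structure the analysis
assumes: a noisy monotone canopy->biomass relation, optional per-site
intercept offsets, extra attenuation noise on the "secondary" fractions
(weeds and individual clover species, whose vertical distribution in the
sward decouples canopy from biomass), and a canopy coverage that saturates
with yield above roughly 2000 kg/ha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

FRACTIONS = ("grass", "white_clover", "red_clover", "weed")
#: dry-matter content assumed for small fresh samples with no dry weighing
SMALL_SAMPLE_DM_CONTENT = 0.25
SMALL_SAMPLE_FRESH_G = 5.0
QUADRAT_AREA_M2 = 0.25

#: calibration column pairs: predictor (canopy) -> response (biomass)
_COLUMNS = {
    "clover": ("canopy_clover", "bm_clover"),
    "grass": ("canopy_grass", "bm_grass"),
    "weed": ("canopy_weed", "bm_weed"),
    "white_clover": ("canopy_white", "bm_white"),
    "red_clover": ("canopy_red", "bm_red"),
}


@dataclass
class BiomassSample:
    """One hand-sorted quadrat sample (weights in grams)."""

    site: str
    cut: int
    fresh_g: dict
    dry_g: dict
    date: str | None = None
    sample_id: str | None = None

    def resolved_dry(self) -> dict:
        """Dry weights after the small-sample 25% dry-matter rule."""
        out = {}
        for f in FRACTIONS:
            fresh = float(self.fresh_g.get(f, 0.0) or 0.0)
            dry = self.dry_g.get(f)
            if dry is None or (isinstance(dry, float) and np.isnan(dry)):
                if fresh < SMALL_SAMPLE_FRESH_G:
                    dry = SMALL_SAMPLE_DM_CONTENT * fresh
                else:
                    raise ValueError(
                        f"{f}: missing dry weight for fresh {fresh} g >= "
                        f"{SMALL_SAMPLE_FRESH_G} g")
            if dry > fresh + 1e-9:
                raise ValueError(f"{f}: dry weight exceeds fresh weight")
            out[f] = float(dry)
        return out


def dry_matter_fractions(sample: BiomassSample) -> dict:
    """Relative dry-matter fractions p_f and the dry-matter yield.

    Returns ``{fraction: p_f, ..., "yield_kg_ha": ...}``; an all-zero sample
    is flagged (``valid`` False, fractions NaN) rather than raising.
    """
    dry = sample.resolved_dry()
    total = sum(dry.values())
    out: dict = {"valid": total > 0}
    if total <= 0:
        for f in FRACTIONS:
            out[f] = float("nan")
        out["yield_kg_ha"] = 0.0
        return out
    for f in FRACTIONS:
        out[f] = dry[f] / total
    # g / 0.25 m^2 -> kg / ha  (1 g m^-2 = 10 kg ha^-1)
    out["yield_kg_ha"] = total / QUADRAT_AREA_M2 * 10.0
    return out


@dataclass
class CalibrationModel:
    """First-order linear canopy->biomass calibration."""

    fraction: str
    slope: float
    intercept: float
    r2: float
    n: int
    n_excluded: int = 0
    residuals: np.ndarray | None = None
    conf_int: dict = field(default_factory=dict)  # 95% CIs for slope/intercept
    degenerate: bool = False

    def predict(self, canopy_fraction):
        return self.intercept + self.slope * np.asarray(canopy_fraction, float)


def _prepare(data: pd.DataFrame, fraction: str):
    if fraction not in _COLUMNS:
        raise ValueError(f"unknown fraction {fraction!r}")
    xcol, ycol = _COLUMNS[fraction]
    ok = data[xcol].notna() & data[ycol].notna()
    return data.loc[ok, xcol].to_numpy(float), data.loc[ok, ycol].to_numpy(float), int((~ok).sum())


def fit_calibration(data: pd.DataFrame, fraction: str = "clover") -> CalibrationModel:
    """OLS of the biomass fraction on the canopy fraction (intercept included).

    Rows with undefined canopy metrics (empty canopy) are excluded and
    counted in ``n_excluded``.  A constant predictor is flagged degenerate.
    """
    x, y, n_excl = _prepare(data, fraction)
    if x.size < 3:
        raise ValueError("need at least 3 rows with defined metrics")
    if np.ptp(x) == 0:
        warnings.warn("constant predictor: calibration degenerate")
        return CalibrationModel(fraction, float("nan"), float(np.mean(y)),
                                float("nan"), int(x.size), n_excl, degenerate=True)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return CalibrationModel(
        fraction,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        n=int(x.size),
        n_excluded=n_excl,
        residuals=np.asarray(res.resid),
        conf_int={"intercept": tuple(ci[0]), "slope": tuple(ci[1])},
    )


def r2_decomposition(data: pd.DataFrame, fraction: str = "clover",
                     group_by: str = "site") -> pd.DataFrame:
    """Per-group calibration R^2 (groups: site, cut, site_x_cut, or all).

    Groups with fewer than 3 usable rows are omitted with a note column.
    """
    keys = {"site": ["site"], "cut": ["cut"], "site_x_cut": ["site", "cut"],
            "all": []}
    if group_by not in keys:
        raise ValueError("group_by must be site, cut, site_x_cut or all")
    rows = []
    groups = [(("all",), data)] if group_by == "all" else data.groupby(keys[group_by])
    for name, sub in groups:
        label = name if isinstance(name, tuple) else (name,)
        x, y, _ = _prepare(sub, fraction)
        if x.size < 3 or np.ptp(x) == 0:
            rows.append({"group": label, "n": int(x.size), "r2": np.nan,
                         "note": "omitted (n<3 or degenerate)"})
            continue
        model = fit_calibration(sub, fraction)
        rows.append({"group": label, "n": model.n, "r2": model.r2, "note": ""})
    return pd.DataFrame(rows)


def loso_validate(data: pd.DataFrame, fraction: str = "clover") -> pd.DataFrame:
    """Leave-one-site-out validation.

    For each site, the calibration is fitted on the other sites and used to
    predict the held-out site; the mean absolute error is reported in
    percentage points of biomass fraction.
    """
    sites = sorted(data["site"].unique())
    if len(sites) < 2:
        raise ValueError("LOSO needs at least 2 sites")
    xcol, ycol = _COLUMNS[fraction]
    rows = []
    for site in sites:
        train = data[data["site"] != site]
        test = data[data["site"] == site]
        model = fit_calibration(train, fraction)
        x, y, _ = _prepare(test, fraction)
        pred = model.predict(x)
        mae_points = float(np.mean(np.abs(pred - y))) * 100.0
        rows.append({"site": site, "n": int(x.size), "mae_points": mae_points,
                     "slope": model.slope, "intercept": model.intercept})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic paired data generator
# ---------------------------------------------------------------------------

def synth_biomass_pairs(
    n_per_site: int = 220,
    sites=("A", "B", "C", "D"),
    slope: float = 0.9,
    intercept: float = 0.05,
    noise_sd: float = 0.05,
    site_offsets: dict | None = None,
    secondary_noise_sd: float = 0.10,
    yield_range_kg_ha: tuple = (50.0, 7500.0),
    yield_saturation_kg_ha: float = 800.0,
    coverage_noise_sd: float = 0.04,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a paired canopy-metrics / biomass-fraction dataset.

    The clover biomass fraction follows ``intercept + slope * canopy + site
    offset + N(0, noise_sd)`` clipped to [0, 1]; canopy clover fractions are
    drawn Uniform(0.02, 0.9) (pure stands of either species are rare in
    practice).  Weed and clover-species channels carry extra attenuation
    noise, emulating their uneven vertical distribution in the sward.
    Canopy coverage follows a saturating response ``1 - exp(-yield /
    yield_saturation)`` so that coverage is uninformative for yields above
    roughly 2000 kg/ha.
    """
    rng = np.random.default_rng(seed)
    site_offsets = site_offsets or {}
    rows = []
    for site in sites:
        off = float(site_offsets.get(site, 0.0))
        canopy_clover = rng.uniform(0.02, 0.9, n_per_site)
        bm_clover = np.clip(intercept + slope * canopy_clover + off
                            + rng.normal(0, noise_sd, n_per_site), 0, 1)
        canopy_weed = rng.uniform(0.0, 0.15, n_per_site)
        canopy_grass = np.clip(1.0 - canopy_clover - canopy_weed, 0, 1)
        bm_weed = np.clip(0.8 * canopy_weed
                          + rng.normal(0, secondary_noise_sd, n_per_site) * 0.3, 0, 1)
        bm_grass = np.clip(1.0 - bm_clover - bm_weed, 0, 1)
        # species split of clover, noisier than the total (vertical layering)
        split = np.clip(rng.beta(5, 5, n_per_site)
                        + rng.normal(0, secondary_noise_sd, n_per_site), 0, 1)
        canopy_white = canopy_clover * split
        canopy_red = canopy_clover - canopy_white
        bm_split = np.clip(split + rng.normal(0, secondary_noise_sd, n_per_site), 0, 1)
        bm_white = bm_clover * bm_split
        bm_red = bm_clover - bm_white
        yield_kg = np.exp(rng.uniform(np.log(yield_range_kg_ha[0]),
                                      np.log(yield_range_kg_ha[1]), n_per_site))
        coverage = np.clip(1.0 - np.exp(-yield_kg / yield_saturation_kg_ha)
                           + rng.normal(0, coverage_noise_sd, n_per_site), 0, 1)
        for i in range(n_per_site):
            rows.append({
                "sample_id": f"{site}{i:04d}", "site": site,
                "cut": int(rng.integers(1, 6)),
                "canopy_coverage": coverage[i],
                "canopy_clover": canopy_clover[i],
                "canopy_grass": canopy_grass[i],
                "canopy_weed": canopy_weed[i],
                "canopy_white": canopy_white[i],
                "canopy_red": canopy_red[i],
                "bm_clover": bm_clover[i], "bm_grass": bm_grass[i],
                "bm_weed": bm_weed[i], "bm_white": bm_white[i],
                "bm_red": bm_red[i],
                "yield_kg_ha": yield_kg[i],
            })
    return pd.DataFrame(rows)
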