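"""Report tooling over the published campaign summary tables.

Two small tables ship with the package: the plot-trial site comparison
(per-site sample counts by camera system) and the per-field summary of the
two large-scale survey campaigns (area, acquisition time, image count,
image density, mapping speed).  The functions here recompute the derived
quantities - per-site and grand sample totals, total mapped area, total
image count, image-density consistency, and the median mapping capacity -
from the raw table cells.

One survey row (farm B, field 4, May campaign) prints an image count that
is inconsistent with its own area and density cells (it duplicates the
neighbouring field's count); :func:`density_consistency` flags it, and the
survey totals are reported both as the raw column sum and with the flagged
rows' image counts excluded.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: relative mismatch between images/area and the printed density above
#: which a row is considered internally inconsistent (printed cells are
#: rounded from unrounded areas, so ~2% slack is ordinary)
DENSITY_MISMATCH_RTOL = 0.05


def _read(name: str) -> pd.DataFrame:
    with resources.files("swardmap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_plot_trials() -> pd.DataFrame:
    """Plot-trial site table (one row per experimental site)."""
    return _read("plot_trial_sites.csv")


def load_survey_fields() -> pd.DataFrame:
    """Large-scale survey table (one row per mapped field)."""
    return _read("survey_fields.csv")


_CAMERA_COLS = ("samples_nikon_d810a_led", "samples_sony_a7_ring",
                "samples_sony_a7_speedlight")


def plot_trial_totals(df: pd.DataFrame | None = None) -> dict:
    """Per-site biomass sample totals recomputed from camera-system counts."""
    df = load_plot_trials() if df is None else df
    per_site = {r.site: int(sum(getattr(r, c) for c in _CAMERA_COLS))
                for r in df.itertuples()}
    return {"per_site": per_site,
            "grand_total": int(sum(per_site.values())),
            "printed_per_site": {r.site: int(r.total_samples) for r in df.itertuples()}}


def density_consistency(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rows whose image count disagrees with their own area x density cells."""
    df = load_survey_fields() if df is None else df
    recomputed = df["images"] / df["area_ha"]
    rel = np.abs(recomputed - df["density_per_ha"]) / df["density_per_ha"]
    out = df.assign(recomputed_density=recomputed, rel_mismatch=rel)
    return out[rel > DENSITY_MISMATCH_RTOL].reset_index(drop=True)


def survey_totals(df: pd.DataFrame | None = None) -> dict:
    """Campaign-level aggregates recomputed from the per-field table."""
    df = load_survey_fields() if df is None else df
    bad = density_consistency(df)
    bad_keys = set(zip(bad["campaign"], bad["farm"], bad["field"]))
    consistent = df[~df.apply(
        lambda r: (r["campaign"], r["farm"], r["field"]) in bad_keys, axis=1)]
    dens = consistent["density_per_ha"]
    return {
        "n_fields": int(len(df)),
        "total_area_ha": float(df["area_ha"].sum()),
        "total_images_raw_sum": int(df["images"].sum()),
        "total_images_consistent": int(consistent["images"].sum()),
        "median_speed_ha_per_h": float(df["speed_ha_per_h"].median()),
        "density_min_typical": float(dens[dens > 100].min()),
        "density_max_typical": float(dens.max()),
        "n_inconsistent_rows": int(len(bad)),
    }
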