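"""Published summary tables from a northern-Greece European wildcat survey.

These are the per-site survey-effort summaries and the density-class
reclassification table of an eight-site, 292-station camera-trap study of
the European wildcat (*Felis silvestris*) in northern Greece (2015-2021
field seasons). They provide real-world anchor points for the package's
summary arithmetic: encounter rates, naive occupancy, grand totals,
across-site dispersion, and density-class population bounds can all be
recomputed from these columns. The raw detection records themselves are not
public; the synthetic-data generator stands in for them.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["survey_sites", "density_classes"]


def survey_sites() -> pd.DataFrame:
    """Per-site survey effort and wildcat detections.

    ``occupied_stations`` is the number of camera stations with at least one
    independent wildcat detection; naive occupancy is occupied / total
    stations. ``deployment_mean``/``deployment_sd`` summarize per-station
    deployment durations in days.
    """
    rows = [
        # site, trap_nights, n_stations, deployment_mean, deployment_sd,
        # detections, occupied_stations
        ("Evros", 244, 10, 24.4, 6.1, 8, 7),
        ("Nestos", 528, 17, 31.1, 2.6, 17, 9),
        ("Koronia-Volvi", 2231, 64, 35.4, 6.7, 70, 20),
        ("Axios", 230, 9, 25.6, 7.2, 6, 4),
        ("Amyntaio", 1535, 42, 35.7, 7.2, 88, 24),
        ("Olympos", 390, 6, 65.0, 0.0, 11, 6),
        ("Prespes", 2500, 62, 40.3, 12.4, 65, 14),
        ("Pindos", 3253, 82, 39.7, 13.1, 54, 19),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "site",
            "trap_nights",
            "n_stations",
            "deployment_mean",
            "deployment_sd",
            "detections",
            "occupied_stations",
        ],
    )


def density_classes() -> pd.DataFrame:
    """Density-class areas and conservative density ranges for the study area.

    Relative-abundance classes (absent/low/medium/high at thresholds 0.0001,
    1.5 and 20 on a 0-62 scale) with their mapped areas in northern Greece
    and the assigned density ranges in individuals/km^2.
    """
    rows = [
        ("absent", 0.0, 1e-4, 1055.0, 0.0, 0.0),
        ("low", 1e-4, 1.5, 30580.0, 0.05, 0.1),
        ("medium", 1.5, 20.0, 11945.0, 0.1, 0.2),
        ("high", 20.0, 62.0, 5410.0, 0.15, 0.3),
    ]
    return pd.DataFrame(
        rows,
        columns=["class", "lam_low", "lam_high", "area_km2", "density_low", "density_high"],
    )
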