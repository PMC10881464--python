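"""Reference group-summary tables from the eight-rabbit calvarial study.

The study this analysis was designed around compared four treatments of
8 mm calvarial critical-size defects in eight rabbits — spontaneous blood
clot, Pure Coral Mineral (PCM), and two deproteinized bovine bone minerals
(DBBMb, low-temperature processed; DBBMc, high-temperature processed) —
and published its per-region results only as group summaries
(mean % +/- SD with n). Those printed summaries are themselves valid inputs
to the summary-statistics routines in :mod:`defectvol.stats`, so they are
shipped here as tidy tables for reanalysis and as worked-example data.

Micro-CT measures (n = 8 defects per group):

* ``regeneration_pct`` — bone volume per region / pristine-bone volume of
  the equal-volume control annulus, x100;
* ``graft_fraction_pct`` — graft / (bone + graft) per region, x100.

Histology measures (blood and PCM n = 8, DBBMb and DBBMc n = 7; graft
present only in the DBBM groups):

* ``ct_pct`` / ``bone_pct`` — connective tissue resp. bone area over
  (bone + connective tissue), x100 (they sum to 100 by construction);
* ``graft_pct`` — graft area over (bone + connective tissue), x100.
"""

from __future__ import annotations

import pandas as pd

from .stats import GroupSummary

__all__ = ["micro_ct_summary", "histology_summary", "group_summaries"]

_MICRO_CT = [
    # group, region, measure, n, mean, sd
    ("blood", "inner", "regeneration_pct", 8, 23.57, 18.01),
    ("blood", "middle", "regeneration_pct", 8, 44.72, 18.30),
    ("blood", "outer", "regeneration_pct", 8, 76.54, 14.29),
    ("PCM", "inner", "regeneration_pct", 8, 15.88, 12.00),
    ("PCM", "middle", "regeneration_pct", 8, 45.34, 19.89),
    ("PCM", "outer", "regeneration_pct", 8, 82.23, 9.60),
    ("DBBMb", "inner", "regeneration_pct", 8, 51.67, 27.98),
    ("DBBMb", "middle", "regeneration_pct", 8, 64.77, 19.18),
    ("DBBMb", "outer", "regeneration_pct", 8, 84.55, 12.07),
    ("DBBMc", "inner", "regeneration_pct", 8, 53.32, 20.62),
    ("DBBMc", "middle", "regeneration_pct", 8, 65.80, 16.20),
    ("DBBMc", "outer", "regeneration_pct", 8, 89.79, 8.44),
    ("blood", "inner", "graft_fraction_pct", 8, 0.00, 0.00),
    ("blood", "middle", "graft_fraction_pct", 8, 0.00, 0.00),
    ("blood", "outer", "graft_fraction_pct", 8, 0.00, 0.00),
    ("PCM", "inner", "graft_fraction_pct", 8, 15.07, 8.08),
    ("PCM", "middle", "graft_fraction_pct", 8, 7.24, 3.65),
    ("PCM", "outer", "graft_fraction_pct", 8, 3.32, 1.73),
    ("DBBMb", "inner", "graft_fraction_pct", 8, 50.03, 14.50),
    ("DBBMb", "middle", "graft_fraction_pct", 8, 40.92, 8.26),
    ("DBBMb", "outer", "graft_fraction_pct", 8, 28.21, 8.34),
    ("DBBMc", "inner", "graft_fraction_pct", 8, 49.53, 13.31),
    ("DBBMc", "middle", "graft_fraction_pct", 8, 42.79, 10.52),
    ("DBBMc", "outer", "graft_fraction_pct", 8, 25.54, 11.49),
]

_HISTOLOGY = [
    ("blood", "inner", "ct_pct", 8, 60.39, 19.38),
    ("blood", "middle", "ct_pct", 8, 56.66, 23.72),
    ("blood", "outer", "ct_pct", 8, 50.45, 14.32),
    ("PCM", "inner", "ct_pct", 8, 73.03, 17.31),
    ("PCM", "middle", "ct_pct", 8, 67.54, 15.06),
    ("PCM", "outer", "ct_pct", 8, 69.46, 12.99),
    ("DBBMb", "inner", "ct_pct", 7, 63.28, 14.69),
    ("DBBMb", "middle", "ct_pct", 7, 46.08, 13.73),
    ("DBBMb", "outer", "ct_pct", 7, 36.73, 6.90),
    ("DBBMc", "inner", "ct_pct", 7, 67.84, 17.36),
    ("DBBMc", "middle", "ct_pct", 7, 57.87, 17.29),
    ("DBBMc", "outer", "ct_pct", 7, 35.58, 15.90),
    ("blood", "inner", "bone_pct", 8, 39.61, 19.38),
    ("blood", "middle", "bone_pct", 8, 43.34, 23.72),
    ("blood", "outer", "bone_pct", 8, 49.55, 14.32),
    ("PCM", "inner", "bone_pct", 8, 26.98, 17.31),
    ("PCM", "middle", "bone_pct", 8, 32.46, 15.06),
    ("PCM", "outer", "bone_pct", 8, 30.54, 12.99),
    ("DBBMb", "inner", "bone_pct", 7, 36.72, 14.69),
    ("DBBMb", "middle", "bone_pct", 7, 53.92, 13.73),
    ("DBBMb", "outer", "bone_pct", 7, 63.27, 6.90),
    ("DBBMc", "inner", "bone_pct", 7, 32.16, 17.36),
    ("DBBMc", "middle", "bone_pct", 7, 42.13, 17.29),
    ("DBBMc", "outer", "bone_pct", 7, 64.42, 15.90),
    ("DBBMb", "inner", "graft_pct", 7, 67.44, 52.25),
    ("DBBMb", "middle", "graft_pct", 7, 49.36, 30.12),
    ("DBBMb", "outer", "graft_pct", 7, 30.13, 16.71),
    ("DBBMc", "inner", "graft_pct", 7, 51.44, 17.45),
    ("DBBMc", "middle", "graft_pct", 7, 50.87, 21.39),
    ("DBBMc", "outer", "graft_pct", 7, 41.38, 17.94),
]

_COLUMNS = ["group", "region", "measure", "n", "mean", "sd"]


def micro_ct_summary() -> pd.DataFrame:
    """Published micro-CT group summaries (tidy: group, region, measure, n, mean, sd)."""
    return pd.DataFrame(_MICRO_CT, columns=_COLUMNS)


def histology_summary() -> pd.DataFrame:
    """Published histomorphometry group summaries (same tidy schema)."""
    return pd.DataFrame(_HISTOLOGY, columns=_COLUMNS)


def group_summaries(table: pd.DataFrame, region: str, measure: str) -> list[GroupSummary]:
    """Extract :class:`~defectvol.stats.GroupSummary` objects for one
    region x measure slice of a tidy summary table, in table order."""
    sub = table[(table.region == region) & (table.measure == measure)]
    if sub.empty:
        raise KeyError(f"no rows for region={region!r}, measure={measure!r}")
    return [
        GroupSummary(label=r.group, n=int(r.n), mean=float(r.mean), sd=float(r.sd))
        for r in sub.itertuples()
    ]
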