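#!/usr/bin/env python
"""Build the per-winter covariate table: storm stats, PCA storminess, lags.

Reads the simulated raw inputs (storm tracks, daily wind/wave maxima, raw
covariates), screens tracks (>48 h, >1000 km), computes the per-winter storm
characteristics, collapses them to the PC1 storminess index, fills population
count gaps by the moving average, adds 1-winter SST lags, standardises the
continuous covariates and reports the collinearity screen.
"""

from pathlib import Path

import pandas as pd

from stormsurv import storms
from stormsurv.covariates import (
    add_lags_and_standardize,
    correlation_screen,
    fill_population,
    storminess_pc1,
)

DATA = Path("scratch/data")
RESULTS = Path("results")
RESULTS.mkdir(exist_ok=True)
BOX = (-9.0, 1.0, 43.0, 57.0)
YEARS = list(range(1985, 2021))

tracks = storms.read_tracks_csv(DATA / "tracks.csv")
kept = storms.filter_tracks(tracks)
daily = pd.read_csv(DATA / "daily_wind_wave.csv", parse_dates=["date"])
stats = storms.winter_storm_table(kept, BOX, YEARS, daily)
stats.to_csv(RESULTS / "storm_stats.csv", index=False)
print(f"{len(kept)}/{len(tracks)} tracks kept; mean storms/winter "
      f"{stats['n_storms'].mean():.1f}")

storm_vars = stats.drop(columns=["winter", "winter_start_year"]).astype(float)
pca = storminess_pc1(storm_vars.fillna(storm_vars.mean()))
pca.loadings.to_csv(RESULTS / "storminess_pca_loadings.csv")
pd.DataFrame(
    {"component": pca.loadings.columns, "explained_fraction": pca.explained}
).to_csv(RESULTS / "storminess_pca_variance.csv", index=False)
print(f"PC1 explains {100 * pca.explained[0]:.1f}% of storm-variable variance")

raw = pd.read_csv(DATA / "covariates_raw.csv")
filled, flag = fill_population(raw["population"])
raw["population"] = filled
print(f"population gaps filled for winters "
      f"{raw.loc[flag, 'winter_start_year'].tolist()}")

raw["PC1"] = pca.pc1.to_numpy()
cov = add_lags_and_standardize(
    raw,
    lag_columns=("sSST", "wSST"),
    standardize_columns=("PC1", "sSST", "wSST", "lag_sSST", "lag_wSST",
                         "naoi", "population"),
)
# storm characteristics join the table standardised, for the storm-model set
for c in ("n_storms", "mean_intensity", "mean_duration", "mean_gap",
          "days_wind_ge_30", "days_wind_ge_35", "days_wave_ge_5"):
    cov[c] = (stats[c] - stats[c].mean()) / stats[c].std(ddof=1)
cov.to_csv(RESULTS / "covariates.csv", index=False)

screen = correlation_screen(
    cov[["PC1", "sSST", "wSST", "naoi", "population"]], threshold=0.7
)
screen.to_csv(RESULTS / "covariate_correlations.csv", index=False)
flagged = screen[screen["flagged"]]
if len(flagged):
    print("collinear pairs (|r| > 0.7), not combined in models:")
    print(flagged.to_string(index=False))
print(f"covariate table written to {RESULTS}/covariates.csv")
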