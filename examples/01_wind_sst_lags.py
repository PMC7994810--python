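"""Weekly cross-correlation lags between wind and SST along an upwelling plume.

Generates an 11-year daily wind record with pulsed high-wind events and a
matching SST record at four boxes whose (negative) response to wind is
delayed by 1, 2, 2 and 2 weeks — the spatial progression of a plume from
its upwelling source to downstream locations. The pipeline reduces both
to weekly resolution, removes seasonal cycle and trend, cross-correlates
per spring–summer season, and reports the lag of the strongest negative
correlation with its cross-season mean +/- SE.
"""

import plumelag as pl

config = pl.AnalysisConfig(heatwave_seasons=(2016, 2018))

wind = pl.gen_wind(pl.WindSimParams(), seed=1)
plume = pl.PlumeSimParams(heatwave_offsets={2016: 1.2, 2018: 0.9})
sst = pl.gen_sst(wind, plume, seed=2)

results = pl.wind_sst_lag_analysis(wind, sst, config)

print("wind -> SST cross-correlation (negative sign convention)")
print(f"{'box':>14}  injected  peak_lag  peak_ACF   SE(at peak)")
for box in plume.plume_order:
    r = results[box]
    se = r.se_acf[r.peak_lag]
    print(
        f"{box:>14}  {plume.box_lags_weeks[box]:>8}  {r.peak_lag:>8}  "
        f"{r.peak_acf:>8.3f}   {se:.3f}"
    )
print(
    "\nEach row: the lag (weeks) at which colder SST best follows stronger"
    "\nwind, averaged over non-heatwave seasons; it should recover the"
    "\ninjected box lag, increasing with distance downstream."
)
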