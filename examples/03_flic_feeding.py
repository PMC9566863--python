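"""Feeding-event detection and the hunger-driven-feeding contrast.

Simulates 12 flies per state x diet cell on the FLIC (starved flies
feed at twice the fed bout rate), calls events with the >40 a.u. rule
over the 3-hr window, and runs the two-way ANOVA with Šidák-corrected
fed-vs-starved contrasts per diet.
"""

from flyquant import flic, synth

summaries = []
i = 0
for diet in ("NF", "HSD"):
    for state, rate in (("fed", 0.05), ("stv", 0.10)):
        for fly in range(12):
            spec = synth.FlicSceneSpec(bout_rate=rate, seed=100 + i)
            series, _ = synth.generate_flic_series(
                spec, well=f"{diet}-{state}-{fly}", diet=diet, state=state)
            events = flic.detect_events(series, threshold=40.0, mode="runs")
            summaries.append(flic.summarize_window(events, series))
            i += 1

res = flic.hdf_contrast(summaries, between="diet")
print("per-cell mean feeding events (first 3 hr):")
for (state, diet), s in sorted(res.anova.cell_stats.items()):
    print(f"  {diet:3s} {state}: {s['mean']:5.1f}  (n = {s['n']})")
print(f"ANOVA state effect: F = {res.anova.effects['state'].statistic:.1f}, "
      f"p = {res.anova.effects['state'].p_value:.2e}")
for _, row in res.contrasts.iterrows():
    print(f"  {row['diet']}: stv - fed = {row['diff']:+.1f} events, "
          f"Šidák p = {row['p_adj']:.3g}, HDF {'yes' if row['hdf'] else 'no'}")
print("HDF = starved flies feeding significantly more than fed ones;")
print("its loss under chronic high-sugar diet is the study's key behaviour.")
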