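"""Simulate a camera-trap survey shaped like a small savanna park study.

Builds the bundled survey fixture — 30 stations at ~2.1 km spacing, 53 daily
occasions with ~10% failed trap-nights, a 370 km^2 park inside a buffered
habitat grid — writes the four input CSVs, and prints what a field team
would tally at the end of the season.
"""

from pathlib import Path

import bayescr as b

out = Path("scratch/example_survey")
out.mkdir(parents=True, exist_ok=True)

traps, mask, enc, truth = b.make_lmnp_fixture(seed=5, pixel_km=1.0, buffer_km=12.0)

b.write_traps(traps, out / "traps.csv")
b.write_encounters(enc, traps, out / "encounters.csv", sex_path=out / "sex.csv")
b.write_mask(mask, out / "mask.csv")

rate = b.detection_rate(enc, traps)
print(f"stations: {traps.n_stations}, occasions: {traps.n_occasions}")
print(f"usable trap-nights: {traps.total_effort} "
      f"(of {traps.effort.size} scheduled)")
print(f"true population in the state space: {truth.n_true} "
      f"({truth.region_counts['park']} inside the park)")
print(f"detected individuals: {enc.n}  (never seen: {truth.n_dropped})")
print(f"detection rate: {rate:.2f} individuals per 100 trap-nights")
print(f"files written to {out}/")

# The detection rate is the raw field tally n / effort; everything density-
# related needs the spatial model fitted in the next example.
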