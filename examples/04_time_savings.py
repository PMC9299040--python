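"""Modelling screening time from per-band stopwatch measurements.

Summarises measured seconds-per-record by relevance band and
extrapolates the hours saved by a given screening reduction.
"""

import citescreen as cs

# stopwatch samples (seconds per record), five records per band:
# high-relevance abstracts take minutes, low-relevance ones seconds
measured = {
    "90-99": [138, 155, 220, 278, 280],
    "20-29": [8, 25, 60, 76, 130],
    "13": [3, 5, 7, 5, 15],
}
print(f"{'band':>6} {'n':>3} {'min':>5} {'max':>5} {'mean':>7} {'total':>7}")
for row in cs.band_time_summary(measured):
    print(f"{row.band:>6} {row.n:>3} {row.min_s:>5.0f} {row.max_s:>5.0f} "
          f"{row.mean_s:>7.1f} {row.total_s:>7.0f}")

mean_low = cs.band_time_summary({"13": measured["13"]})[0].mean_s
for n_unscreened in (1000, 12954):
    hours, seconds = cs.estimate_time_saved(n_unscreened, mean_low)
    print(f"not screening {n_unscreened} low-relevance records at "
          f"{mean_low:.0f} s each saves ~{hours} h ({seconds:.0f} s)")
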