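"""From raw fluorescence traces to a genotype call.

Renders a simulated sample as four dye-channel signal arrays (Gaussian peaks
on a constant baseline, in-lane size ladder in the LIZ channel), then runs
detection, ladder calibration, size assignment, binding and calling.
"""

import cefacall as cc
from cefacall.genotyper import get_catalog

panel = cc.default_panel()
catalog = get_catalog(panel)
zero = cc.zero_noise_params()

truth = "--SEA/aa;bN/bN"
sample = cc.simulate_peak_table(truth, panel, zero, seed=8)
trace = cc.simulate_trace(sample, panel, zero)
print(f"trace: {trace.scan_count} scans x 4 channels, truth {truth}")

peaks = cc.detect_peaks(trace, min_height=200, min_prominence=100, window=51)
print(f"detected {len(peaks)} peaks "
      f"({sum(1 for p in peaks if p.dye == 'LIZ')} in the ladder channel)")

calibration = cc.fit_size_ladder(
    [p for p in peaks if p.dye == "LIZ"], panel.ladder_sizes
)
print(f"ladder: {len(calibration.ladder_points)} points matched, "
      f"max residual {abs(calibration.residuals).max():.3f} bp")

sized = cc.assign_sizes(peaks, calibration)
call = cc.call_sample(trace, panel, catalog)
m = call.measurement
print(f"a1/a2 = {m.a_ratio:g}, Y1/Y2 = {m.y_ratio:g}")
print(f"-> {call.status}: {call.labels(panel)}")
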