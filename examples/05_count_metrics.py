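"""Count-accuracy metrics on a small set of observed/predicted pairs.

Shows MAE, NMSPE, predictive deviance, Spearman and r² on hand-made
records, including the zero-observed convention in the deviance.
"""

from tasselcount import CountRecord, metrics_report, nmspe, predictive_deviance

records = [
    CountRecord("plot_01", 10, 8.0),
    CountRecord("plot_02", 20, 25.0),
    CountRecord("plot_03", 14, 13.0),
    CountRecord("plot_04", 31, 28.5),
    CountRecord("plot_05", 6, 7.5),
]
rep = metrics_report(records)
print(f"MAE      : {rep.mae:.3f}   (mean |observed - predicted|)")
print(f"NMSPE    : {rep.nmspe:.3f}   (chi-square-like; 0 iff exact)")
print(f"PD       : {rep.pd:.3f}   (Poisson-style deviance)")
print(f"Spearman : {rep.spearman:.3f}")
print(f"r²       : {rep.r_squared:.3f}")

print("\nzero-observed convention:",
      predictive_deviance([CountRecord("p", 0, 3.0)]),
      "(leading log term dropped, 2·(0-(0-3)) = 6)")
print("floor guard:", nmspe([CountRecord("p", 3, 0.0)]),
      "(T̂=0 floored at 0.5: (3-0)²/0.5 = 18)")
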