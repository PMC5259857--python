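"""Run a full simulated agreement study: automatic vs manual measurement.

Generates a 30-case synthetic study (landmark placement noise 1.5 px,
manual-arm noise 0.5 mm / 1.0 deg), then runs the paired analysis:
per-parameter means, SDs and paired t-tests, maximum absolute errors by
kind, and the mean-relative-agreement accuracy percentage.
"""

from cephkit import compare_tables, default_template, generate_paired_study

table = generate_paired_study(default_template())
rows, summary = compare_tables(table, alpha=0.05)

print(f"{'parameter':10s} {'auto mean':>9s} {'manual mean':>11s} {'p':>8s}  max|err|")
for row in rows:
    print(
        f"{row.parameter:10s} {row.auto_mean:9.2f} {row.manual_mean:11.2f} "
        f"{row.p_value:8.3f}  {row.max_abs_error:.2f} {row.unit}"
    )

print(f"\ncases: {summary['n_cases']}, parameters flagged at alpha=0.05: "
      f"{summary['n_significant']}")
print(f"max |auto - manual|: "
      f"{summary['max_abs_error_by_kind']['linear']:.2f} mm (linear), "
      f"{summary['max_abs_error_by_kind']['angular']:.2f} deg (angular)")
print(f"accuracy: {summary['accuracy_percent']:.1f}%  "
      f"({summary['accuracy_definition']})")
print(
    "\nWith no injected bias the two arms differ only by noise, so flags at "
    "alpha=0.05 are false positives and should appear for roughly 1 in 20 "
    "parameters."
)
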