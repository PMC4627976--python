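"""Audit the packaged knowledge base and enumerate every decision path.

Prints the validation verdict, the exhaustive path-catalog summary
(counts are tallied from the enumeration, never read from metadata), the
depth extremes with the tests that realize them, and the per-source
provenance of the 85 catalogued tests.
"""

from statselect import (
    enumerate_paths,
    load_packaged_kb,
    provenance_report,
    shortest_path_to,
    validate_kb,
)

kb = load_packaged_kb()

report = validate_kb(kb)
print(f"validation passed: {report.passed} "
      f"({len(report.findings)} findings, {len(report.errors())} errors)")

s = enumerate_paths(kb).summary
print(f"paths={s.n_paths}  questions={s.n_questions_used}  "
      f"recommendations={s.n_distinct_recommendations}  "
      f"tests={s.n_tests_covered}")
print(f"depth range {s.depth_min}-{s.depth_max}, histogram {s.depth_histogram}")

vec, d = shortest_path_to(kb, "ordered logistic regression")
print(f"shortest route to ordered logistic regression: {vec} ({d} questions)")
vec, d = shortest_path_to(kb, "Chi-square test for trend")
print(f"deepest recommendation, chi-square test for trend: {vec} ({d} questions)")

print("\nsource trees (tests contributed):")
for name, info in provenance_report(kb).items():
    base = "  <- base tree" if info["is_base"] else ""
    print(f"  {name}: {info['n_tests']}{base}")
# The summary counts are the tree's structural fingerprint: any edit to
# the KB document that changes topology or coverage shows up here.
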