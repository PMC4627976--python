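"""Replay the worked blood-pressure decision path through the unified tree.

A researcher measured systolic blood pressure in 15 women before and after
oral-contraceptive use; the within-pair differences are not normally
distributed, and the two measurement sets are dependent (same subjects).
The corresponding answer column is yes, no, yes, no, no, no, no.
"""

from statselect import load_packaged_kb, render_trace, run_answers

kb = load_packaged_kb()
trace = run_answers(kb, "ynynnnn")
print(render_trace(trace, kb))
print()
print(f"Steps to recommendation: {len(trace.steps)}")
print("Flipping the final (independence) answer instead gives:")
flipped = run_answers(kb, "ynynnny")
print("  ->", flipped.outcome.label(kb))
# The 7-step path ends at the nonparametric paired-samples leaf; with
# independent samples the same facts lead to the Mann-Whitney U branch.
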