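# statselect

Choosing the right statistical test is one of the most error-prone steps
in biomedical research: the choice depends on the number of variables and
samples, whether the samples are dependent, whether a normality assumption
is tenable, the measurement scale, and a handful of special cases
(binomial outcomes, person-time data, survival times, …).  Published
test-selection flowcharts each cover only a slice of this space.

`statselect` ships a **unified binary decision tree** that integrates ten
published selection trees (Rosner's, the most comprehensive, serving as
the base) into one apparatus: **44 yes/no questions** routing to **59
distinct recommendations** that cover **85 statistical tests**, with a
**44-term glossary** and per-test provenance back to the source trees.
Every root-to-leaf route takes between **4 and 11 questions**.  The
package is aimed at researchers without a statistician at hand, and at
tool builders who want an auditable, machine-readable test recommender.

It is a *recommender*, not an analysis engine: it tells you which test
fits your design and data; it does not run that test (the one exception:
its dataset profiler runs Shapiro–Wilk and Levene checks to *answer* the
tree's assumption questions from your data).

## The model

The knowledge base is a rooted strict binary tree. Internal nodes carry a
question `q` and two targets; leaves carry a recommendation
`R = {t_1, …, t_k}` of one or more tests appropriate under every answer
on the path. For an answer vector `a ∈ {yes, no}^d` the engine computes

    leaf(a) = target(… target(target(root, a_1), a_2) …, a_d)

and succeeds iff the vector lands exactly on a leaf. Structure is never
taken on faith: `validate_kb` audits acyclicity, binary totality,
reachability and orphans, and `enumerate_paths` recomputes all counts by
exhaustive depth-first traversal (yes-branch first).

The profiler turns a data table plus a hypothesis configuration into
answers: scale types from the columns, dependency from the declared
design, and normality from Shapiro–Wilk at level α (on the within-pair
differences for paired designs) — each answer annotated with the evidence
that produced it.

## Worked example

The classic paired scenario — systolic blood pressure measured in 15
women before and after oral-contraceptive use, with non-normal
differences — answers the questions yes, no, yes, no, no, no, no:

```python
from statselect import load_packaged_kb, run_answers, render_trace

kb = load_packaged_kb()
trace = run_answers(kb, "ynynnnn")
print(render_trace(trace, kb))
```

prints

```
Step  Answer  Question
----  ------  --------
   1  yes     Does your data set have only one variable?
   2  no      Is it a "one sample" problem?
   3  yes     Is it a "two samples" problem?
   4  no      Does your data appear to be normally distributed (bell-shaped curve)?
   5  no      Does your data have a binomial distribution?
   6  no      Do you have person-time data?
   7  no      Are your samples (=groups) independent?
Recommendation — use Wilcoxon signed rank test or Sign test
```

Seven questions suffice: one variable measured twice on the same
subjects, no normality, not binomial, not person-time, dependent groups —
so the nonparametric paired-samples leaf. Flipping only the final answer
(independent groups) lands on the Mann–Whitney U (Wilcoxon rank sum)
recommendation instead. `examples/` contains this and three more
narrative scripts (structure audit, data-driven profiling, toy-KB
round-trip), each runnable with `python examples/<name>.py`.

The same functionality is available from a shell:

```bash
statselect batch ynynnnn          # batch inference, exit codes 2/3 for short/long vectors
statselect wizard                 # interactive: y/n, '?' explanation, 'g <term>', 'b' back
statselect report                 # validation + path catalog + provenance
statselect export-dot --out tree.dot
```

## Layout

- `src/statselect/data/unified_tree.yaml` — the knowledge base (schema-
  validated YAML; JSON accepted interchangeably)
- `src/statselect/model.py`, `io.py` — domain types, reader/writer
- `src/statselect/session.py` — interactive/batch traversal with undo
- `src/statselect/analysis.py` — validation, path enumeration, DOT export
- `src/statselect/profiler.py` — data-driven question answering
- `src/statselect/fixtures.py` — toy-KB and synthetic-dataset generators
- `docs/methods.md` — modeling decisions, parameters, limitations
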