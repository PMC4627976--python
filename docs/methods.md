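# Methods

## The knowledge base

The packaged document (`src/statselect/data/unified_tree.yaml`) encodes a
strict binary decision tree for statistical test selection. Its design
targets, all verified computationally by the test suite rather than
asserted in metadata:

- 44 distinct yes/no questions, each with an on-demand explanation and
  links into a 44-term glossary;
- 59 distinct recommendation records whose union covers 85 catalogued
  test methods;
- 10 source trees with per-test provenance — Rosner's tree (36 tests) is
  the base; the other nine (Jaykaran, Twycross & Shields, Gunawardena,
  Marusteri & Bacarea, Gaddis & Gaddis, Nayak & Hazra, McCrum-Gardner,
  UCLA, Mertler & Vannatta) contribute the remainder;
- every root-to-leaf route takes between 4 and 11 questions; ordered
  logistic regression is reachable in the minimum 4, and the chi-square
  test for trend sits on the unique deepest, 11-question branch.

Structural choices worth recording:

**Strict tree, shared recommendations.** Each decision node has exactly
one parent; where the same conclusion is reached from different contexts
(e.g. Fisher's exact test from the two-sample branch and from the
categorical-association branch) the *leaves* are distinct but point to
the same recommendation id. The tree has 80 internal nodes and 81 leaves;
path counts therefore exceed the 59 distinct recommendation ids, and the
catalog reports both numbers.

**Question reuse.** The 44 questions are a bank, not a per-node text:
recurring probes (normality, sample independence, binomial outcome,
expected cell counts) appear at several nodes. This mirrors how the
branch logic repeats across sub-problems and keeps the question bank
reviewable.

**Synonym collapse.** Mann–Whitney U / Wilcoxon rank sum count as one
test with an alias, as do spelling variants (Cochran/Cochrane,
Dunnett/Dunnet, Kolmogorov–Smirnov/-Simirnov). Name resolution is case-,
whitespace- and dash-insensitive, and validation rejects any string that
would resolve to two tests.

**Catalogue boundaries.** The 85-test catalogue includes the multivariate
methods contributed by the UCLA and Mertler & Vannatta source trees
(MANOVA/MANCOVA families, discriminant, factor and canonical analysis,
PCA, path analysis), reached through a dedicated several-outcomes branch.
Methods outside all ten source trees (e.g. Hotelling's T²) are absent and
deliberately unresolvable. Eight catalogued methods (Sign test, ROC
analysis, Bartlett's and Levene's tests, Kaplan–Meier, Shapiro–Wilk,
Kendall's tau, the median test) carry no source-tree provenance: they
belong to the unified tree itself rather than to any single source.

**Identifiers and format.** Stable human-readable slugs
(`q_one_variable`, `r_wilcoxon_sign`, `t_mann_whitney_u`) keep the YAML
diffable. Branch targets are spelled `yes_target`/`no_target` because
bare `yes:`/`no:` keys are booleans in YAML 1.1. Serialization sorts
records by id, so saving is deterministic and save→load is the identity
on structure. Loading enforces schema and referential closure with
record-scoped error messages; deeper audits (cycles, reachability,
orphans, alias ambiguity) are *findings* from `validate_kb` so that a
suspect document can still be loaded and inspected. Severities: `error`
breaks traversal or a core contract; `warning` marks orphans.

**Depth convention.** Path depth counts the questions answered from the
root up to and including the last one before the recommendation; the
worked paired-samples example is depth 7 under this convention.

## Traversal semantics

Sessions are immutable values; `answer` and `go_back` return new
sessions, making the undo-inverse property (`go_back ∘ answer = id`)
literal structural equality, and the answer history is the single source
of truth (replaying it from the root reproduces the position). Going
back after completing reverts the session to in-progress; the abandoned
sub-path is discarded, not cached. Batch inference (`run_answers`)
accepts compact vectors over `{y,n}` and insists on landing exactly on a
leaf: exhausting the vector early reports the pending question, and
overshooting reports the recommendation already reached plus the surplus
count — distinct CLI exit codes (2 and 3) for scripting.

## The dataset profiler

`profile_dataset` maps a table plus a `HypothesisConfig` to answers:

- **Scale types**: exactly two distinct non-missing values → binary; a
  declared ordering in `ordered_levels` → ordinal (ordinality is
  semantics, never inferred from syntax); numeric with more than six
  distinct non-integer-coded values → continuous; otherwise nominal.
- **Normality**: Shapiro–Wilk at `normality_alpha` (default 0.05), run on
  the within-pair differences for paired designs. The sample size is
  recorded alongside the verdict and n < 30 is flagged in the
  justification, but the decision stays test-based.
- **Dependency** comes from the declared design; paired before/after
  columns count as *one* conceptual variable measured twice.
- **Variance homogeneity**: for two independent groups, Levene's test
  answers the equal-variances question.
- **Binomial approximation**: for binary variables, n·p̂·(1−p̂) ≥ 5 decides
  the normal-approximation question.
- **Hypothesis-driven questions** (trend, agreement, post-hoc stage,
  known population variance, goodness-of-fit goals) are answered from the
  config's `goal`/`design`/`extra_answers`, never guessed; person-time is
  answered "no" only when the analysis variable is a continuous or binary
  measurement (which cannot be person-time exposure), and is otherwise
  unanswerable without an explicit `person_time` setting.

Missing data are deleted pairwise within the analyzed columns and the
deletion count is visible in the justifications. The profiler performs no
routing of its own: it walks the tree and looks answers up, so its
outcome provably equals `run_answers` on the extracted vector.

Calibration: because the normality answer is exactly a Shapiro–Wilk
decision, its type-I behavior matches the nominal level; the suite
verifies 0.05 ± 0.02 over 1,000 simulated normal samples of n = 30.

## Synthetic data

`make_paired_dataset` emulates a small pre/post measurement study:
baseline values N(120, 10²) (resembling systolic blood pressure in mm Hg),
within-pair differences `effect + 3·ε`. With `noise="normal"`, ε is
standard normal; with `noise="heavy_tailed"`, ε is Student-t with **1**
degree of freedom. One degree of freedom (rather than a milder 2) is used
because the generator's contract is that Shapiro–Wilk at α = 0.05 flags
the differences as non-normal with high probability at n = 15; measured
rejection rates are ≈ 0.77 for t₁ versus ≈ 0.44 for t₂, so only t₁
honors the contract. The property is asserted over repeated seeds, not
per seed. The default worked scenario uses n_pairs = 15, matching the
15-subject paired design the tree's worked example describes.

What the generator does *not* emulate: measurement rounding beyond 0.1,
missing values, covariates, or any group structure beyond one paired or
two independent samples — so passing tests show the decision logic and
assumption checks behave correctly, not that the profiler handles messy
real-world tables.

`make_toy_kb` builds complete or randomly pruned binary trees (seeded,
deterministic; the yes-most path always realizes the full requested
depth) with recommendations cycled over leaves — the substrate for the
brute-force enumeration oracle up to depth 12 (4,096 vectors).

## Numerical and interface choices

- Shapiro–Wilk and Levene come from `scipy.stats`; no statistical
  primitive is reimplemented.
- DOT export writes Graphviz text directly (questions as boxes, leaves as
  filled ovals); shared recommendation leaves render once with multiple
  incoming edges.
- Enumeration is depth-first, yes-branch first; `shortest_path_to`
  breaks depth ties toward that order.
- Answer parsing accepts y/yes/n/no in any case; interactive mode
  re-prompts on anything else, batch mode errors (exit code 5).
- The KB language tag lives in `metadata.language`; all v1 text is
  English.

## Known limitations

- The full 44-question tree topology beyond the printed fragments of its
  source material is a reconstruction constrained by the documented
  structural facts; alternative topologies satisfying the same
  constraints exist.
- The profiler evaluates normality on the first analysis variable (or
  paired differences), not per group; severely different group shapes are
  not separately flagged.
- Single-step undo only; multi-step undo is composition.
- No session persistence: saving the answer vector *is* the persistent
  form, by the history-as-truth invariant.
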