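"""Generators for toy knowledge bases and synthetic tabular datasets.

Everything here is deterministic under a fixed seed.  Toy KBs always pass
validation and realize their requested counts exactly; generated datasets
have the statistical structure their parameters declare (paired
before/after measurements with a chosen shift and either Gaussian or
heavy-tailed noise).  The heavy-tailed generator uses a scaled Student-t
with 1 degree of freedom, which a Shapiro–Wilk check at alpha 0.05
reliably flags as non-normal even at n = 15.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    DecisionNode,
    GlossaryEntry,
    KnowledgeBase,
    Question,
    Recommendation,
    SourceTree,
    TestMethod,
)

__all__ = ["ToyKbSpec", "make_toy_kb", "make_paired_dataset"]


@dataclass(frozen=True)
class ToyKbSpec:
    """Specification for a synthetic complete-or-pruned binary toy tree.

    ``depth`` is the number of questions on the longest root-to-leaf path.
    With ``complete=True`` every path has exactly that depth (2**depth
    leaves); otherwise a seeded random subset of internal nodes is
    truncated into leaves early (at least one full-depth path survives).
    ``n_recommendations`` distinct recommendation records are cycled over
    the leaves, so several leaves may share a recommendation id, as in the
    packaged tree.
    """

    depth: int
    complete: bool = True
    n_recommendations: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_recommendations < 1:
            raise ValueError("n_recommendations must be >= 1")


def make_toy_kb(spec: ToyKbSpec) -> KnowledgeBase:
    """Build a synthetic toy KB; deterministic for a given spec."""
    rng = np.random.default_rng(spec.seed)
    questions: dict[str, Question] = {}
    nodes: dict[str, DecisionNode] = {}
    leaf_slots: list[str] = []          # leaf placeholders, in DFS order
    counter = {"n": 0}

    def new_node(depth_left: int) -> str:
        counter["n"] += 1
        nid = f"n{counter['n']:03d}"
        qid = f"q{counter['n']:03d}"
        questions[qid] = Question(
            id=qid,
            text=f"Synthetic question {counter['n']}?",
            category="special_case",
            explanation=f"Toy branching point {counter['n']}.",
        )
        # targets filled in by build(); leaf placeholders patched at the end
        nodes[nid] = DecisionNode(id=nid, question_id=qid,
                                  yes_target="", no_target="")
        return nid

    def build(depth_left: int, force_full: bool) -> str:
        """Return a target id: either a new node or a leaf placeholder."""
        truncate = (
            depth_left == 0
            or (not spec.complete and not force_full and depth_left > 0
                and rng.random() < 0.35 and depth_left < spec.depth)
        )
        if truncate:
            slot = f"LEAF{len(leaf_slots)}"
            leaf_slots.append(slot)
            return slot
        nid = new_node(depth_left)
        # keep the yes-most path at full depth so max depth is realized
        yes = build(depth_left - 1, force_full)
        no = build(depth_left - 1, False)
        nodes[nid] = DecisionNode(id=nid, question_id=nodes[nid].question_id,
                                  yes_target=yes, no_target=no)
        return nid

    root = build(spec.depth, force_full=True)

    # recommendations and tests, cycled over leaves in DFS order
    n_rec = min(spec.n_recommendations, len(leaf_slots))
    tests = {
        f"t{i:03d}": TestMethod(
            id=f"t{i:03d}", canonical_name=f"Synthetic test {i}",
            family="nonparametric", sources=("Toy",),
        )
        for i in range(1, n_rec + 1)
    }
    recommendations = {
        f"r{i:03d}": Recommendation(id=f"r{i:03d}", test_ids=(f"t{i:03d}",))
        for i in range(1, n_rec + 1)
    }
    rec_ids = sorted(recommendations)
    leaf_map = {slot: rec_ids[i % n_rec] for i, slot in enumerate(leaf_slots)}
    for nid, node in list(nodes.items()):
        nodes[nid] = DecisionNode(
            id=nid, question_id=node.question_id,
            yes_target=leaf_map.get(node.yes_target, node.yes_target),
            no_target=leaf_map.get(node.no_target, node.no_target),
        )

    return KnowledgeBase(
        metadata={"name": "toy-kb", "version": "1",
                  "depth": spec.depth, "seed": spec.seed},
        root=root,
        nodes=nodes,
        questions=questions,
        recommendations=recommendations,
        tests=tests,
        glossary={"toy": GlossaryEntry("toy", "A synthetic placeholder term.")},
        sources={"Toy": SourceTree(name="Toy", test_ids=tuple(sorted(tests)),
                                   is_base=True)},
    )


def make_paired_dataset(n_pairs: int, effect: float = 0.0,
                        noise: str = "normal", seed: int = 0,
                        scale: float = 10.0, baseline: float = 120.0
                        ) -> pd.DataFrame:
    """Synthetic paired before/after measurements for one group of subjects.

    Emulates a pre/post intervention design on a continuous measurement
    (defaults resemble systolic blood pressure in mm Hg, 15 subjects).
    ``effect`` shifts the after-measurement; ``noise`` controls the
    distribution of the within-pair differences: ``"normal"`` draws
    Gaussian differences, ``"heavy_tailed"`` draws scaled Student-t with
    1 degree of freedom (Cauchy-like tails), which normality tests reject
    with high probability even in small samples.

    Returns a DataFrame with columns ``subject``, ``before``, ``after``.
    """
    if n_pairs < 3:
        raise ValueError("n_pairs must be >= 3")
    if noise not in ("normal", "heavy_tailed"):
        raise ValueError(f"unknown noise kind {noise!r}")
    rng = np.random.default_rng(seed)
    before = baseline + scale * rng.standard_normal(n_pairs)
    if noise == "normal":
        diff = effect + 3.0 * rng.standard_normal(n_pairs)
    else:
        diff = effect + 3.0 * rng.standard_t(df=1, size=n_pairs)
    return pd.DataFrame({
        "subject": np.arange(1, n_pairs + 1),
        "before": np.round(before, 1),
        "after": np.round(before + diff, 1),
    })
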