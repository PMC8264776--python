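"""Synthetic ground-truth regulatory networks and expression data.

The generator emulates the statistical structure the inference pipeline
assumes: a modular network in which each regulatory "program" is a block
of TFs that jointly regulate a disjoint block of target genes, additive
linear target expression with Gaussian noise, and a condition effect
(mean shift delta) applied to the TFs of designated stress programs.
Stress-program TFs form the labeled positive class, mirroring a curated
set of stress-response regulators; the program id doubles as a family
tag so family-matched baselines can be formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import ExpressionMatrix, LabelSet, RegulatorSet


@dataclass
class GroundTruth:
    """A planted modular regulatory network.

    true_edges maps (regulator, target) -> signed weight. Target blocks
    are disjoint; every target has at least one regulator; positive TFs
    are exactly the TFs of the stress-designated programs.
    """

    true_edges: dict[tuple[str, str], float]
    program_of_tf: dict[str, int]
    targets_of_program: dict[int, tuple[str, ...]]
    positive_tfs: frozenset[str]
    condition_effect: float
    noise_sd: float
    background_edge_rate: float

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for block in self.targets_of_program.values():
            if seen & set(block):
                raise ValidationError("target blocks must be disjoint")
            seen |= set(block)
        regulated = {t for (_, t) in self.true_edges}
        orphans = seen - regulated
        if orphans:
            raise ValidationError(f"target(s) with no regulator: {sorted(orphans)[:5]}")
        if not self.positive_tfs <= set(self.program_of_tf):
            raise ValidationError("positive_tfs must be a subset of the TFs")

    @property
    def tf_ids(self) -> list[str]:
        return sorted(self.program_of_tf)

    @property
    def target_ids(self) -> list[str]:
        return sorted(g for block in self.targets_of_program.values() for g in block)

    @property
    def gene_ids(self) -> list[str]:
        return self.tf_ids + self.target_ids

    def regulator_set(self) -> RegulatorSet:
        return RegulatorSet(self.tf_ids)


def simulate_grn(
    n_programs: int = 4,
    tfs_per_program: int = 5,
    targets_per_program: int = 50,
    p_bg: float = 0.01,
    weight_scale: float = 1.0,
    seed: int = 0,
    n_stress_programs: int = 1,
    delta: float = 2.0,
    sigma: float = 0.5,
    tf_tf_edges: bool = False,
) -> GroundTruth:
    """Plant a modular GRN.

    Every TF of program p regulates every target of p's block with
    weight ~ Normal(weight_scale, 0.1*weight_scale) and random sign;
    cross-program TF->target edges are added independently with
    probability ``p_bg``. TFs of the first ``n_stress_programs``
    programs form the positive class. With ``tf_tf_edges`` the stress
    programs additionally regulate one TF of each other program, for
    stress-testing direction handling (off by default: the consensus
    construction assumes no feedback loops).
    """
    if n_programs < 1 or tfs_per_program < 1 or targets_per_program < 1:
        raise ValidationError("counts must be >= 1")
    if not (0 <= p_bg < 1):
        raise ValidationError("p_bg must be in [0, 1)")
    if not (1 <= n_stress_programs <= n_programs):
        raise ValidationError("n_stress_programs must be in 1..n_programs")
    if weight_scale <= 0 or sigma <= 0:
        raise ValidationError("weight_scale and sigma must be > 0")
    rng = np.random.default_rng(seed)

    width_t = len(str(n_programs * tfs_per_program))
    width_g = len(str(n_programs * targets_per_program))
    program_of_tf: dict[str, int] = {}
    targets_of_program: dict[int, tuple[str, ...]] = {}
    for p in range(n_programs):
        for i in range(tfs_per_program):
            program_of_tf[f"TF{p * tfs_per_program + i + 1:0{width_t}d}"] = p
        targets_of_program[p] = tuple(
            f"G{p * targets_per_program + j + 1:0{width_g}d}"
            for j in range(targets_per_program)
        )

    def draw_weight() -> float:
        w = rng.normal(weight_scale, 0.1 * weight_scale)
        return float(w if rng.random() < 0.5 else -w)

    true_edges: dict[tuple[str, str], float] = {}
    for tf, p in sorted(program_of_tf.items()):
        for tgt in targets_of_program[p]:
            true_edges[(tf, tgt)] = draw_weight()
    if p_bg > 0:
        for tf, p in sorted(program_of_tf.items()):
            for q, block in targets_of_program.items():
                if q == p:
                    continue
                hits = rng.random(len(block)) < p_bg
                for tgt, hit in zip(block, hits):
                    if hit:
                        true_edges[(tf, tgt)] = draw_weight()

    positive = frozenset(
        tf for tf, p in program_of_tf.items() if p < n_stress_programs
    )
    if tf_tf_edges:
        tfs_by_prog: dict[int, list[str]] = {}
        for tf, p in sorted(program_of_tf.items()):
            tfs_by_prog.setdefault(p, []).append(tf)
        for p in range(n_stress_programs):
            src = tfs_by_prog[p][0]
            for q in range(n_programs):
                if q == p:
                    continue
                true_edges[(src, tfs_by_prog[q][0])] = draw_weight()

    return GroundTruth(
        true_edges=true_edges,
        program_of_tf=program_of_tf,
        targets_of_program=targets_of_program,
        positive_tfs=positive,
        condition_effect=delta,
        noise_sd=sigma,
        background_edge_rate=p_bg,
    )


def simulate_expression(
    gt: GroundTruth,
    n_control: int = 75,
    n_stress: int = 75,
    seed: int = 0,
) -> ExpressionMatrix:
    """Draw expression: TF profiles i.i.d. Normal(0,1) per sample, with
    ``delta`` added to positive-program TFs in stress samples; each
    target is the weighted sum of its regulators plus Normal(0, sigma)
    noise. Samples are labeled control/stress."""
    if not gt.true_edges:
        raise ValidationError("ground truth has no edges")
    if n_control + n_stress < 4:
        raise ValidationError("need at least 4 samples in total")
    rng = np.random.default_rng(seed)
    tfs = gt.tf_ids
    targets = gt.target_ids
    n = n_control + n_stress
    condition = np.array(["control"] * n_control + ["stress"] * n_stress)

    tf_expr = rng.normal(0.0, 1.0, size=(len(tfs), n))
    tf_index = {t: i for i, t in enumerate(tfs)}
    stress_mask = condition == "stress"
    for tf in gt.positive_tfs:
        tf_expr[tf_index[tf], stress_mask] += gt.condition_effect

    # regulators may include TFs regulating other TFs; resolve targets after TFs
    expr = np.zeros((len(tfs) + len(targets), n))
    expr[: len(tfs)] = tf_expr
    gene_index = {g: i for i, g in enumerate(tfs + targets)}
    incoming: dict[str, list[tuple[str, float]]] = {}
    for (reg, tgt), w in gt.true_edges.items():
        incoming.setdefault(tgt, []).append((reg, w))
    # TF targets first (depend only on base TF profiles), then gene targets
    for tgt in sorted(incoming, key=lambda g: (g not in tf_index, g)):
        contrib = sum(
            w * expr[gene_index[reg]] for reg, w in sorted(incoming[tgt])
        )
        noise = rng.normal(0.0, gt.noise_sd, size=n)
        if tgt in tf_index:
            expr[gene_index[tgt]] = expr[gene_index[tgt]] + contrib
        else:
            expr[gene_index[tgt]] = contrib + noise

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    values = pd.DataFrame(expr, index=tfs + targets, columns=sample_ids)
    cond = pd.Series(condition, index=sample_ids)
    return ExpressionMatrix(values=values, condition=cond)


def export_labels(gt: GroundTruth) -> LabelSet:
    """Positive-program TFs -> positive, the rest -> negative.

    Family tags cut across programs: the i-th TF of every program
    shares family ``F{i}``. Real TF families are not aligned with
    regulatory programs, and a family-matched negative control is only
    a genuine null when matching the positive class's family
    composition does not reproduce the positive class itself.
    """
    assignments = {
        tf: ("positive" if tf in gt.positive_tfs else "negative")
        for tf in gt.tf_ids
    }
    rank_in_program: dict[int, int] = {}
    family: dict[str, str] = {}
    for tf in sorted(gt.program_of_tf):
        p = gt.program_of_tf[tf]
        i = rank_in_program.get(p, 0)
        family[tf] = f"F{i}"
        rank_in_program[p] = i + 1
    return LabelSet(assignments=assignments, family=family)


def true_modules(gt: GroundTruth):
    """The planted target blocks as a gene-set collection (for module
    recovery checks)."""
    from .types import GeneSetCollection

    sets = {
        f"TRUE{p:02d}": (f"planted program {p}", tuple(block))
        for p, block in sorted(gt.targets_of_program.items())
    }
    return GeneSetCollection(sets=sets)
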