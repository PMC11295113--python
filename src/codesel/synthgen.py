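"""Synthetic hierarchical code data with known ground truth.

Real administrative code data is private, so every stage of the pipeline
runs on generated data that reproduces its statistical skeleton: a
balanced code tree whose synthetic code strings encode their own path
(``R0.1.2`` is the child 2 of child 1 of root 0, so depth is verifiable
from the string); patients who carry latent comorbidity factors, each
emitting a fixed set of correlated leaf codes across dated records;
optional deterministically co-firing sibling codes (redundancy, on top
of the parent implication added later by ancestor closure); independent
noise codes; and a rare binary outcome driven by a sparse set of codes
through a logistic model whose intercept is calibrated by bisection to a
target prevalence.

The generator returns the ground truth (factor code sets, outcome codes
and weights, planted sibling groups) so that recovery experiments can
score selections against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import CodeHierarchy, CodeNode, CodeSystem


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults give a small but structured cohort
    with a rare (5%) outcome, matching the low-prevalence regime of
    administrative mortality data."""

    n_patients: int = 300
    records_per_patient: float = 6.0        # mean of 1 + Poisson(mean - 1)
    hierarchy_shape: tuple[int, int, int] = (2, 3, 4)   # (roots, branching, levels)
    n_latent: int = 5                       # latent comorbidity factors
    codes_per_factor: int = 6
    factor_activation: float = 0.35         # P(patient carries a factor)
    emission_prob: float = 0.9              # P(active factor emits a code per record-batch)
    redundancy_rate: float = 0.0            # P(a factor code gets a co-firing sibling)
    outcome_codes: int = 5
    outcome_weight: float = 1.5             # log-odds per outcome code
    outcome_prevalence: float = 0.05
    noise_flip: float = 0.01                # P(random leaf added per record)
    span_days: int = 360                    # event dates span this many days
    window_days: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("factor_activation", "emission_prob", "redundancy_rate", "noise_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.outcome_prevalence < 0.5:
            raise ValueError("outcome_prevalence must be in (0, 0.5)")


@dataclass
class SynthTruth:
    """Ground truth of one generated cohort."""

    generator_codes: list[list[str]]                   # per latent factor
    outcome_codes_and_weights: dict[str, float]
    sibling_groups: list[tuple[str, str]]              # (source, always-co-firing partner)
    hierarchy: CodeHierarchy = field(repr=False, default=None)


def generate_hierarchy(shape: tuple[int, int, int], seed: int = 0) -> CodeHierarchy:
    """Balanced synthetic forest of ``(n_roots, branching, n_levels)``.

    Deterministic; the seed is accepted for interface symmetry.  Code
    strings are path-encoded: root ``R1``, its children ``R1.0``,
    ``R1.1``, ...
    """
    n_roots, branching, n_levels = shape
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    hier = CodeHierarchy()
    frontier = []
    for r in range(n_roots):
        code = f"R{r}"
        hier.nodes[code] = CodeNode(code=code, system=CodeSystem.SYNTH, depth=0)
        frontier.append(code)
    for level in range(1, n_levels):
        nxt = []
        for parent in frontier:
            for i in range(branching):
                code = f"{parent}.{i}"
                hier.nodes[code] = CodeNode(
                    code=code, system=CodeSystem.SYNTH, parent=parent, depth=level)
                nxt.append(code)
        frontier = nxt
    return hier


def leaves_of(hierarchy: CodeHierarchy) -> list[str]:
    parents = {n.parent for n in hierarchy.nodes.values() if n.parent is not None}
    return sorted(c for c in hierarchy.nodes if c not in parents)


def generate_records(config: SynthConfig, hierarchy: CodeHierarchy
                     ) -> tuple[pd.DataFrame, SynthTruth]:
    """Latent-factor record stream over a given hierarchy.

    Each patient independently carries each factor with probability
    ``factor_activation`` (at least one is forced); every record of an
    active patient emits each of the factor's leaf codes with probability
    ``emission_prob``.  Codes flagged for redundancy drag a designated
    sibling along deterministically; noise adds independent random
    leaves.  Byte-identical output for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    leaves = leaves_of(hierarchy)
    need = config.n_latent * config.codes_per_factor
    if need > len(leaves):
        raise ValueError(f"hierarchy has {len(leaves)} leaves; need {need}")
    pool = [str(c) for c in rng.permutation(leaves)]
    factors = [sorted(pool[i * config.codes_per_factor:(i + 1) * config.codes_per_factor])
               for i in range(config.n_latent)]

    # plant deterministically co-firing siblings: a factor code drags its
    # first sibling (same parent, not already in any factor) along
    in_factor = {c for f in factors for c in f}
    children_of: dict[str, list[str]] = {}
    for c in leaves:
        p = hierarchy.nodes[c].parent
        children_of.setdefault(p, []).append(c)
    sibling_groups: list[tuple[str, str]] = []
    partner: dict[str, str] = {}
    for f in factors:
        for code in f:
            if rng.random() < config.redundancy_rate:
                sibs = [s for s in sorted(children_of[hierarchy.nodes[code].parent])
                        if s != code and s not in in_factor and s not in partner.values()]
                if sibs:
                    partner[code] = sibs[0]
                    sibling_groups.append((code, sibs[0]))

    base = pd.Timestamp("2020-01-01")
    rows: list[tuple[str, str, str, str]] = []
    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        active = rng.random(config.n_latent) < config.factor_activation
        if not active.any():
            active[rng.integers(config.n_latent)] = True
        n_rec = 1 + rng.poisson(max(config.records_per_patient - 1.0, 0.0))
        offsets = np.sort(rng.integers(0, config.span_days, size=n_rec))
        offsets[0] = 0      # anchor the patient's first event
        for off in offsets:
            date = (base + pd.Timedelta(days=int(off))).date().isoformat()
            emitted: list[str] = []
            for fi in np.flatnonzero(active):
                for code in factors[fi]:
                    if rng.random() < config.emission_prob:
                        emitted.append(code)
                        if code in partner:
                            emitted.append(partner[code])
            for leaf in leaves:
                if rng.random() < config.noise_flip:
                    emitted.append(leaf)
            for code in sorted(set(emitted)):
                rows.append((pid, date, code, CodeSystem.SYNTH.value))

    records = pd.DataFrame(rows, columns=["patient_id", "date", "code", "system"])

    # outcome codes: concentrated in the leading factor(s), emulating an
    # outcome driven by one comorbidity cluster
    flat = [c for f in factors for c in f]
    chosen = flat[: config.outcome_codes]
    truth = SynthTruth(
        generator_codes=factors,
        outcome_codes_and_weights={c: config.outcome_weight for c in chosen},
        sibling_groups=sibling_groups,
        hierarchy=hierarchy,
    )
    return records, truth


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_outcome(matrix, truth: SynthTruth, config: SynthConfig,
                     seed: int | None = None) -> np.ndarray:
    """Rare binary outcome from a sparse logistic model on outcome codes.

    ``logit(p_i) = intercept + sum_c w_c x_ic``; the intercept is found
    by bisection so the EXPECTED prevalence equals
    ``config.outcome_prevalence``; labels are then drawn seeded.
    """
    cols = []
    weights = []
    for code, w in truth.outcome_codes_and_weights.items():
        if code not in matrix.feature_codes:
            raise ValueError(f"outcome code {code} missing from matrix columns")
        cols.append(matrix.column_of(code))
        weights.append(w)
    score = np.asarray(matrix.values, dtype=float)[:, cols] @ np.asarray(weights)

    target = config.outcome_prevalence
    span = float(np.abs(list(truth.outcome_codes_and_weights.values())).sum()) \
        if truth.outcome_codes_and_weights else 0.0
    lo, hi = -(span + 40.0), span + 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(score + mid).mean() > target:
            hi = mid
        else:
            lo = mid
    intercept = 0.5 * (lo + hi)
    p = _sigmoid(score + intercept)
    achieved = p.mean()
    if abs(achieved - target) > 0.2 * target:
        raise RuntimeError(f"prevalence calibration failed: achieved {achieved:.4f}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return (rng.random(len(p)) < p).astype(np.uint8)


def planted_duplicates(seed: int, n_samples: int = 1024, n_generators: int = 8,
                       duplicates: int = 8, flip: float = 0.02
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Recovery fixture: generator columns expanded into noisy duplicates.

    ``n_generators`` independent Bernoulli(0.5) columns are each copied
    ``duplicates`` times with entrywise flip noise, giving
    ``n_generators * duplicates`` columns whose group structure is known.
    Returns ``(matrix, group_labels)``; two columns are
    generator-equivalent iff they share a label.
    """
    rng = np.random.default_rng(seed)
    gen = (rng.random((n_samples, n_generators)) < 0.5).astype(float)
    cols, groups = [], []
    for g in range(n_generators):
        for _ in range(duplicates):
            noise = rng.random(n_samples) < flip
            cols.append(np.abs(gen[:, g] - noise))
            groups.append(g)
    return np.stack(cols, axis=1), np.asarray(groups)


def planted_redundancy(seed: int, n_samples: int = 512, n_blocks: int = 8,
                       p_block: float = 0.5, p_child: float = 0.7
                       ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Depth-weighting fixture: parent columns implied by their children.

    Each block is a depth-0 parent with two depth-1 children; when the
    block is active each child fires independently and the parent column
    is their union (ancestor closure), so child -> parent holds
    deterministically and the parent is the more general, more
    informative column.  Returns ``(matrix, codes, depths)`` with
    columns ordered parent, child, child per block.
    """
    rng = np.random.default_rng(seed)
    cols, codes, depths = [], [], []
    for b in range(n_blocks):
        active = rng.random(n_samples) < p_block
        c1 = active & (rng.random(n_samples) < p_child)
        c2 = active & (rng.random(n_samples) < p_child)
        cols += [c1 | c2, c1, c2]
        codes += [f"R{b}", f"R{b}.0", f"R{b}.1"]
        depths += [0, 1, 1]
    return np.stack(cols, axis=1).astype(float), codes, np.asarray(depths)


def hierarchy_to_table(hierarchy: CodeHierarchy) -> pd.DataFrame:
    """``code,parent,label`` table form, for the text interchange format."""
    rows = [(c, n.parent or "", n.label) for c, n in sorted(hierarchy.nodes.items())]
    return pd.DataFrame(rows, columns=["code", "parent", "label"])
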