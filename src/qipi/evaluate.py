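"""Coverage/accuracy evaluation, weight training and cross-validation.

A prediction is a set of residue ids; the truth is the annotated interface
residue set of the same domain.  Coverage COV = TP/(TP+FN), accuracy
ACC = TP/(TP+FP), and the training objective is their product F = COV*ACC,
which balances the two competing demands (find many true interface residues,
predict few false ones).

Weight training is an exhaustive grid search over (w1, w2, w3): the patch
component scores of every candidate are precomputed once per case, so each
grid point only re-ranks linear combinations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, ParameterError
from .interface import extract_interface
from .predict import (
    ScoreWeights,
    SurfacePatch,
    generate_patches,
    merge_patches,
    score_patch,
    sidechain_distance_matrix,
)
from .structure import ComplexPartition, ResidueId, Structure, compute_asa, read_structure


@dataclass
class EvalResult:
    """Confusion counts for one prediction with COV/ACC/F.

    Conventions for degenerate sets: empty truth and empty prediction is a
    perfect call (COV = ACC = F = 1); a non-empty prediction against empty
    truth leaves COV undefined (None) with ACC = 0; an empty prediction
    against non-empty truth scores 0 on all three.
    """

    tp: int
    fp: int
    fn: int

    @property
    def cov(self) -> Optional[float]:
        if self.tp + self.fn == 0:
            return 1.0 if self.fp == 0 else None
        return self.tp / (self.tp + self.fn)

    @property
    def acc(self) -> Optional[float]:
        if self.tp + self.fp == 0:
            return 1.0 if self.fn == 0 else 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def f(self) -> Optional[float]:
        c, a = self.cov, self.acc
        if c is None or a is None:
            return None
        return c * a


def evaluate_prediction(predicted: Set[ResidueId], truth: Set[ResidueId]) -> EvalResult:
    """Confusion counts of a predicted residue set against the truth set."""
    predicted, truth = set(predicted), set(truth)
    tp = len(predicted & truth)
    return EvalResult(tp=tp, fp=len(predicted) - tp, fn=len(truth) - tp)


def f_from_cov_acc(cov: float, acc: float) -> float:
    """The training objective F = COV * ACC."""
    return cov * acc


def aggregate(results: Sequence[EvalResult], mode: str = "macro") -> "AggregateResult":
    """Pool per-case results.

    ``macro``: mean of per-case COV and ACC (cases with undefined coverage
    are dropped from the coverage mean), F = mean COV * mean ACC.
    ``micro``: pool TP/FP/FN and apply the formulas once.
    """
    results = list(results)
    if not results:
        raise ParameterError("cannot aggregate an empty result list")
    if mode == "micro":
        pooled = EvalResult(
            tp=sum(r.tp for r in results),
            fp=sum(r.fp for r in results),
            fn=sum(r.fn for r in results),
        )
        return AggregateResult(pooled.cov, pooled.acc, pooled.f, len(results), mode)
    if mode != "macro":
        raise ParameterError(f"unknown aggregation mode {mode!r}")
    covs = [r.cov for r in results if r.cov is not None]
    accs = [r.acc for r in results if r.acc is not None]
    cov = float(np.mean(covs)) if covs else None
    acc = float(np.mean(accs)) if accs else None
    f = cov * acc if cov is not None and acc is not None else None
    return AggregateResult(cov, acc, f, len(results), mode)


@dataclass
class AggregateResult:
    cov: Optional[float]
    acc: Optional[float]
    f: Optional[float]
    n: int
    mode: str


# ---------------------------------------------------------------------------
# Training cases
# ---------------------------------------------------------------------------

@dataclass
class TrainingCase:
    """One unbound domain with its annotated true interface."""

    case_id: str
    structure: Structure  # unbound, ASA computed
    truth: Set[ResidueId]
    pssm: object = None
    _components: Optional[
        List[Tuple[SurfacePatch, Tuple[float, float, float, float]]]
    ] = field(default=None, repr=False)

    def components(self, esol_grid_spacing: float = 0.3):
        """Merged candidate patches with precomputed component scores."""
        if self._components is None:
            struct = self.structure
            if any(r.asa is None for r in struct.residues):
                compute_asa(struct)
            dm = sidechain_distance_matrix(struct)
            merged = merge_patches(generate_patches(struct, dm), struct.total_asa)
            comps = []
            for p in merged:
                score_patch(
                    p, struct, ScoreWeights(0, 0, 0), pssm=self.pssm,
                    include_cons=self.pssm is not None,
                    esol_grid_spacing=esol_grid_spacing,
                )
                comps.append((p, (p.e_res, p.e_hydro, p.e_cons, p.e_sol)))
            self._components = comps
        return self._components

    def evaluate_at(self, weights: ScoreWeights) -> EvalResult:
        """Re-rank precomputed candidates under the weights and evaluate."""
        best = None
        for p, (er, eh, ec, es) in self.components():
            e = er + weights.w1 * eh + weights.w2 * ec + weights.w3 * es
            key = (-e, -len(p), p.sort_key())
            if best is None or key < best[0]:
                best = (key, p)
        return evaluate_prediction(set(best[1].members), self.truth)


@dataclass
class TrainingConfig:
    """Grid-search / cross-validation settings."""

    grid: Dict[str, Sequence[float]] = field(
        default_factory=lambda: {
            "w1": (0.0, 0.25, 0.5, 1.0, 2.0),
            "w2": (0.0, 0.25, 0.5, 1.0, 2.0),
            "w3": (0.0, 0.25, 0.5, 1.0, 2.0),
        }
    )
    folds: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3"):
            if name not in self.grid or len(self.grid[name]) == 0:
                raise ConfigError(f"grid for {name} must be non-empty")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")


@dataclass
class TrainResult:
    weights: ScoreWeights
    objective: float  # mean F at the optimum
    surface: pd.DataFrame  # full objective surface (w1, w2, w3, mean_f)


def mean_objective(cases: Sequence[TrainingCase], weights: ScoreWeights) -> float:
    """Mean per-case F (undefined F counts as 0)."""
    fs = []
    for case in cases:
        f = case.evaluate_at(weights).f
        fs.append(0.0 if f is None else f)
    return float(np.mean(fs))


def train_weights(
    cases: Sequence[TrainingCase], cfg: Optional[TrainingConfig] = None
) -> TrainResult:
    """Exhaustive grid search maximising mean F; ties take the smallest
    (w1, w2, w3) lexicographically."""
    cfg = cfg or TrainingConfig()
    if not cases:
        raise ConfigError("no training cases")
    rows = []
    best: Optional[Tuple[float, Tuple[float, float, float]]] = None
    for w1, w2, w3 in itertools.product(cfg.grid["w1"], cfg.grid["w2"], cfg.grid["w3"]):
        obj = mean_objective(cases, ScoreWeights(w1, w2, w3))
        rows.append({"w1": w1, "w2": w2, "w3": w3, "mean_f": obj})
        key = (-obj, (w1, w2, w3))
        if best is None or key < best:
            best = key
    obj, (w1, w2, w3) = -best[0], best[1]
    return TrainResult(ScoreWeights(w1, w2, w3), obj, pd.DataFrame(rows))


@dataclass
class CrossValResult:
    per_fold: pd.DataFrame  # fold, n_test, cov, acc, f, w1, w2, w3
    mean_cov: float
    sd_cov: float
    mean_acc: float
    sd_acc: float


def cross_validate(
    cases: Sequence[TrainingCase], cfg: Optional[TrainingConfig] = None
) -> CrossValResult:
    """Seeded k-fold cross-validation of the weight training.

    Cases are permuted with the config seed and dealt round-robin into
    folds; each fold is evaluated (macro) with weights trained on the rest.
    """
    cfg = cfg or TrainingConfig()
    cases = list(cases)
    if cfg.folds > len(cases):
        raise ConfigError(f"folds={cfg.folds} exceeds {len(cases)} cases")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(cases))
    assignment = {int(idx): k % cfg.folds for k, idx in enumerate(order)}
    rows = []
    for fold in range(cfg.folds):
        test = [c for i, c in enumerate(cases) if assignment[i] == fold]
        train = [c for i, c in enumerate(cases) if assignment[i] != fold]
        fit = train_weights(train, cfg)
        results = [c.evaluate_at(fit.weights) for c in test]
        agg = aggregate(results, "macro")
        rows.append(
            {
                "fold": fold,
                "n_test": len(test),
                "cov": agg.cov,
                "acc": agg.acc,
                "f": agg.f,
                "w1": fit.weights.w1,
                "w2": fit.weights.w2,
                "w3": fit.weights.w3,
            }
        )
    df = pd.DataFrame(rows)
    return CrossValResult(
        per_fold=df,
        mean_cov=float(df["cov"].mean()),
        sd_cov=float(df["cov"].std(ddof=1)),
        mean_acc=float(df["acc"].mean()),
        sd_acc=float(df["acc"].std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# Case loading (manifest of partitioned complexes)
# ---------------------------------------------------------------------------

def load_cases(manifest_path, base_dir=None, n_points: int = 960) -> List[TrainingCase]:
    """Build training cases from a complex manifest TSV.

    Columns: ``file`` (PDB path, relative to the manifest unless absolute),
    ``side_a`` and ``side_b`` (comma- or empty-separated chain ids).  Each
    complex contributes two cases, one per side: the unbound structure is the
    isolated side, the truth its extracted interface residue set.
    """
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    required = {"file", "side_a", "side_b"}
    if not required <= set(df.columns):
        raise ConfigError(f"manifest must have columns {sorted(required)}")
    cases: List[TrainingCase] = []
    for _, row in df.iterrows():
        path = Path(row["file"])
        if not path.is_absolute():
            path = base / path
        cx = read_structure(path)
        chains_a = set(row["side_a"].replace(",", ""))
        chains_b = set(row["side_b"].replace(",", ""))
        part = ComplexPartition(cx, chains_a, chains_b)
        ann = extract_interface(part, n_points=n_points)
        for side in ("a", "b"):
            unbound = ann.side_structures[side]
            cases.append(
                TrainingCase(
                    case_id=f"{path.stem}:{side}",
                    structure=unbound,
                    truth=set(ann.interface_residues[side]),
                )
            )
    return cases
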