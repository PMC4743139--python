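"""Naive Bayes posterior computation and the one-/two-step predictors.

Posterior for class C given a binary domain profile:

    score(C) = prior(C) * prod_i l_i(C)

where ``l_i(C)`` is the stored presence likelihood when domain i is present
and ``1 - p`` when absent, each clamped into ``[PC, 1 - PC]`` with the
pseudo-count PC (default 0.1) so a single contradictory observation cannot
zero out a class. Scores are accumulated in log space and normalized across
classes. The two-step network first separates anaerobes from
respiration-capable genomes and then splits the latter into aerobe vs.
facultative; under leave-one-out cross-validation both feature selection and
likelihood estimation are redone for every fold with the held-out genome
removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from oxyreq.core_io import (
    BASE_CLASSES,
    ClassScheme,
    LikelihoodTable,
    ONE_STEP_SCHEME,
    PresenceMatrix,
    STEP1_SCHEME,
    STEP2_SCHEME,
    read_likelihood_table,
    write_likelihood_table,
)
from oxyreq.feature_selection import (
    SelectionParams,
    class_frequencies,
    select_class_associated_domains,
)

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class BayesParams:
    """Pseudo-count and prior for posterior computation.

    ``pc_mode='clamp'`` (default) clamps every per-domain likelihood into
    ``[PC, 1-PC]``; ``pc_mode='additive'`` adds PC to each likelihood
    instead (sensitivity-analysis variant). ``prior=None`` means flat.
    """

    pseudo_count: float = 0.1
    prior: tuple[float, ...] | None = None
    pc_mode: str = "clamp"

    def __post_init__(self) -> None:
        if not 0 <= self.pseudo_count < 0.5:
            raise ValueError("pseudo_count must be in [0, 0.5)")
        if self.pc_mode not in ("clamp", "additive"):
            raise ValueError("pc_mode must be 'clamp' or 'additive'")
        if self.prior is not None:
            pr = np.asarray(self.prior, dtype=float)
            if (pr < 0).any() or abs(pr.sum() - 1.0) > 1e-9:
                raise ValueError("prior must be non-negative and sum to 1")

    def prior_for(self, n_classes: int) -> np.ndarray:
        if self.prior is None:
            return np.full(n_classes, 1.0 / n_classes)
        if len(self.prior) != n_classes:
            raise ValueError(
                f"prior has {len(self.prior)} entries for {n_classes} classes"
            )
        return np.asarray(self.prior, dtype=float)


@dataclass
class PosteriorResult:
    """Normalized class posteriors for one genome."""

    genome_id: str | None
    classes: tuple[str, ...]
    posteriors: np.ndarray
    predicted: str
    tie: bool

    def probability(self, cls: str) -> float:
        return float(self.posteriors[self.classes.index(cls)])

    def as_dict(self) -> dict[str, float]:
        return {c: float(p) for c, p in zip(self.classes, self.posteriors)}


def _profile_vector(
    profile: "set[str] | Mapping[str, int] | Sequence[int] | np.ndarray",
    domain_ids: Sequence[str],
) -> np.ndarray:
    """Coerce a profile (present-domain set, mapping, or aligned vector) to 0/1."""
    if isinstance(profile, (set, frozenset)):
        return np.fromiter((d in profile for d in domain_ids), dtype=float)
    if isinstance(profile, Mapping):
        return np.fromiter((1.0 if profile.get(d) else 0.0 for d in domain_ids), float)
    x = np.asarray(profile, dtype=float)
    if x.shape != (len(domain_ids),):
        raise ValueError(
            f"profile vector length {x.shape} does not match table ({len(domain_ids)})"
        )
    return x


def _log_likelihoods(
    table: LikelihoodTable, params: BayesParams
) -> tuple[np.ndarray, np.ndarray]:
    """(log l_present, log l_absent), each shaped (n_domains, n_classes)."""
    p = table.likelihoods
    pc = params.pseudo_count
    if params.pc_mode == "clamp":
        pres = np.clip(p, pc, 1.0 - pc) if pc > 0 else p
        absent = np.clip(1.0 - p, pc, 1.0 - pc) if pc > 0 else 1.0 - p
    else:
        pres = p + pc
        absent = (1.0 - p) + pc
    with np.errstate(divide="ignore"):
        return np.log(pres), np.log(absent)


def posterior(
    profile: "set[str] | Mapping[str, int] | Sequence[int] | np.ndarray",
    table: LikelihoodTable,
    params: BayesParams = BayesParams(),
    genome_id: str | None = None,
) -> PosteriorResult:
    """Posterior over the table's classes for a single presence profile.

    ``profile`` may be a set of present domain accessions, a mapping
    domain -> 0/1, or a 0/1 vector aligned with ``table.domain_ids``.
    Domains in the profile that are absent from the table are ignored.
    """
    if table.is_empty():
        logger.warning("empty likelihood table: posterior equals the prior")
    x = _profile_vector(profile, table.domain_ids)
    post = _posteriors_from_vectors(x[None, :], table, params)[0]
    return _make_result(genome_id, table.classes, post)


def _posteriors_from_vectors(
    X: np.ndarray, table: LikelihoodTable, params: BayesParams
) -> np.ndarray:
    """Normalized posteriors for profile rows X (n, n_domains) -> (n, n_classes)."""
    log_prior = np.log(params.prior_for(len(table.classes)))
    if table.is_empty():
        scores = np.tile(log_prior, (X.shape[0], 1))
    else:
        lp, la = _log_likelihoods(table, params)
        # -inf log-likelihoods (possible only at PC = 0) are tracked apart so
        # that 0 * -inf never poisons the matmul and a zero stays an exact zero
        lp_inf, la_inf = np.isneginf(lp), np.isneginf(la)
        scores = (
            log_prior
            + X @ np.where(lp_inf, 0.0, lp)
            + (1.0 - X) @ np.where(la_inf, 0.0, la)
        )
        zeroed = (X @ lp_inf + (1.0 - X) @ la_inf) > 0
        scores[zeroed] = -np.inf
        # PC = 0 can zero out every class at once; fall back to the prior
        dead = np.isneginf(scores).all(axis=1)
        if dead.any():
            logger.warning(
                "%d profile(s) had zero likelihood under every class; "
                "falling back to the prior", int(dead.sum()),
            )
            scores[dead] = log_prior
    return np.exp(scores - logsumexp(scores, axis=1, keepdims=True))


def _make_result(
    genome_id: str | None, classes: tuple[str, ...], post: np.ndarray
) -> PosteriorResult:
    best = int(np.argmax(post))  # argmax returns the first max: canonical order
    tie = bool(np.sum(post >= post[best] - _TIE_TOL) > 1)
    return PosteriorResult(genome_id, classes, post, classes[best], tie)


# ---------------------------------------------------------------------------
# Trained models
# ---------------------------------------------------------------------------


@dataclass
class OneStepModel:
    """Flat multi-class model: one likelihood table."""

    table: LikelihoodTable
    params: BayesParams = field(default_factory=BayesParams)

    def predict(self, profile, genome_id: str | None = None) -> PosteriorResult:
        return posterior(profile, self.table, self.params, genome_id)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_likelihood_table(self.table, out_dir / "likelihoods.tsv")
        _write_model_config(out_dir, "one-step", self.params, [self.table.classes])

    @classmethod
    def load(cls, model_dir: str | Path) -> "OneStepModel":
        model_dir = Path(model_dir)
        params = _read_model_config(model_dir)
        return cls(read_likelihood_table(model_dir / "likelihoods.tsv"), params)


@dataclass
class TwoStepModel:
    """Nested dichotomy: respiring-vs-anaerobe table, then aerobe-vs-facultative."""

    step1_table: LikelihoodTable
    step2_table: LikelihoodTable | None
    params: BayesParams = field(default_factory=BayesParams)

    def predict_detailed(
        self, profile, genome_id: str | None = None
    ) -> tuple[str, PosteriorResult, PosteriorResult | None]:
        """Returns (final class, step-1 result, step-2 result or None)."""
        p1 = posterior(profile, self.step1_table, self.params, genome_id)
        if p1.predicted == "anaerobe":
            return "anaerobe", p1, None
        if self.step2_table is None:
            raise ValueError(
                "step 1 predicted respiration-capable but no step-2 table is configured"
            )
        p2 = posterior(profile, self.step2_table, self.params, genome_id)
        return p2.predicted, p1, p2

    def predict(self, profile, genome_id: str | None = None) -> PosteriorResult:
        final, p1, p2 = self.predict_detailed(profile, genome_id)
        return p2 if p2 is not None else p1

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_likelihood_table(self.step1_table, out_dir / "step1_likelihoods.tsv")
        schemes = [self.step1_table.classes]
        if self.step2_table is not None:
            write_likelihood_table(self.step2_table, out_dir / "step2_likelihoods.tsv")
            schemes.append(self.step2_table.classes)
        _write_model_config(out_dir, "two-step", self.params, schemes)

    @classmethod
    def load(cls, model_dir: str | Path) -> "TwoStepModel":
        model_dir = Path(model_dir)
        params = _read_model_config(model_dir)
        step2_path = model_dir / "step2_likelihoods.tsv"
        return cls(
            read_likelihood_table(model_dir / "step1_likelihoods.tsv"),
            read_likelihood_table(step2_path) if step2_path.exists() else None,
            params,
        )


def _write_model_config(
    out_dir: Path, mode: str, params: BayesParams, schemes: list[tuple[str, ...]]
) -> None:
    config = {
        "mode": mode,
        "pseudo_count": params.pseudo_count,
        "pc_mode": params.pc_mode,
        "prior": list(params.prior) if params.prior is not None else None,
        "class_schemes": [list(s) for s in schemes],
    }
    (out_dir / "model.json").write_text(json.dumps(config, indent=2) + "\n")


def _read_model_config(model_dir: Path) -> BayesParams:
    path = model_dir / "model.json"
    if not path.exists():
        return BayesParams()
    config = json.loads(path.read_text())
    prior = config.get("prior")
    return BayesParams(
        pseudo_count=config.get("pseudo_count", 0.1),
        prior=tuple(prior) if prior is not None else None,
        pc_mode=config.get("pc_mode", "clamp"),
    )


def load_model(model_dir: str | Path) -> "OneStepModel | TwoStepModel":
    model_dir = Path(model_dir)
    if (model_dir / "step1_likelihoods.tsv").exists():
        return TwoStepModel.load(model_dir)
    return OneStepModel.load(model_dir)


def classify(
    profile, model: "OneStepModel | TwoStepModel", genome_id: str | None = None
) -> PosteriorResult:
    """Apply a trained model to one profile (no cross-validation)."""
    return model.predict(profile, genome_id)


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class PredictionRun:
    """Result of a cross-validated prediction run.

    ``predictions`` maps every evaluated genome to its final class.
    ``posteriors`` holds the final per-class posteriors for one-step runs;
    two-step runs populate ``step1`` for every genome and ``step2`` only for
    genomes that were predicted respiration-capable at step 1.
    """

    mode: str
    classes: tuple[str, ...]
    predictions: dict[str, str]
    posteriors: dict[str, PosteriorResult] = field(default_factory=dict)
    step1: dict[str, PosteriorResult] = field(default_factory=dict)
    step2: dict[str, PosteriorResult] = field(default_factory=dict)
    fold_tables: dict[str, tuple[LikelihoodTable, ...]] = field(default_factory=dict)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.predictions)


def _restrict_to_scheme(
    matrix: PresenceMatrix, labels: Mapping[str, str], scheme: ClassScheme
) -> PresenceMatrix:
    excluded = [
        g for g in matrix.genome_ids if scheme.task_label(labels[g]) is None
    ]
    return matrix.drop_genomes(excluded) if excluded else matrix


def _fold_table(
    train: PresenceMatrix,
    labels: Mapping[str, str],
    scheme: ClassScheme,
    selection_params: SelectionParams,
    global_table: LikelihoodTable | None,
) -> LikelihoodTable:
    """Likelihood table for one training fold.

    With ``global_table`` set (fast mode) only the class frequencies are
    re-estimated on the fold; the selected domain list is reused.
    """
    if global_table is None:
        return select_class_associated_domains(train, labels, scheme, selection_params)
    freqs = class_frequencies(train, labels, scheme)
    pos = {d: j for j, d in enumerate(train.domain_ids)}
    idx = [pos[d] for d in global_table.domain_ids]
    return LikelihoodTable(
        classes=scheme.classes,
        domain_ids=list(global_table.domain_ids),
        likelihoods=freqs[idx],
        associated_class=list(global_table.associated_class),
        t_stats=global_table.t_stats,
        p_values=global_table.p_values,
    )


def predict_one_step_loocv(
    matrix: PresenceMatrix,
    labels: Mapping[str, str],
    params: BayesParams = BayesParams(),
    selection_params: SelectionParams = SelectionParams(),
    scheme: ClassScheme = ONE_STEP_SCHEME,
    refit_selection: bool = True,
    store_tables: bool = False,
) -> PredictionRun:
    """Leave-one-out flat prediction over the scheme's classes.

    For every genome, class-associated domains and their likelihoods are
    recomputed on all remaining genomes before that genome is scored.
    Genomes whose label is excluded by the scheme are dropped entirely
    (the aerobe/anaerobe-only mode passes a two-class scheme here).
    """
    matrix = _restrict_to_scheme(matrix, labels, scheme)
    global_table = (
        None
        if refit_selection
        else select_class_associated_domains(matrix, labels, scheme, selection_params)
    )
    run = PredictionRun(mode="one-step", classes=scheme.classes, predictions={})
    pos = {d: j for j, d in enumerate(matrix.domain_ids)}
    for i, g in enumerate(matrix.genome_ids):
        train = matrix.drop_genomes([g])
        table = _fold_table(train, labels, scheme, selection_params, global_table)
        profile = matrix.values[i, [pos[d] for d in table.domain_ids]].astype(float)
        result = posterior(profile, table, params, genome_id=g)
        run.predictions[g] = result.predicted
        run.posteriors[g] = result
        if store_tables:
            run.fold_tables[g] = (table,)
        if (i + 1) % 50 == 0:
            logger.info("one-step LOOCV: %d/%d folds done", i + 1, matrix.n_genomes)
    return run


def predict_two_step_loocv(
    matrix: PresenceMatrix,
    labels: Mapping[str, str],
    params: BayesParams = BayesParams(),
    selection_params: SelectionParams = SelectionParams(),
    refit_selection: bool = True,
    store_tables: bool = False,
) -> PredictionRun:
    """Leave-one-out nested-dichotomy prediction.

    Step 1 trains respiring-vs-anaerobe on all genomes except the one under
    prediction; genomes predicted anaerobe are final. Step 2 trains on the
    aerobe and facultative genomes only (again excluding the predicted
    genome when applicable) and assigns aerobe or facultative. A truly
    anaerobe genome mispredicted as respiring still receives a step-2 call.
    """
    matrix = _restrict_to_scheme(matrix, labels, STEP1_SCHEME)
    step2_base = _restrict_to_scheme(matrix, labels, STEP2_SCHEME)
    if refit_selection:
        g1 = g2 = None
    else:
        g1 = select_class_associated_domains(matrix, labels, STEP1_SCHEME, selection_params)
        g2 = select_class_associated_domains(step2_base, labels, STEP2_SCHEME, selection_params)
    run = PredictionRun(mode="two-step", classes=BASE_CLASSES, predictions={})
    pos = {d: j for j, d in enumerate(matrix.domain_ids)}
    for i, g in enumerate(matrix.genome_ids):
        row = matrix.values[i]
        train1 = matrix.drop_genomes([g])
        t1 = _fold_table(train1, labels, STEP1_SCHEME, selection_params, g1)
        r1 = posterior(
            row[[pos[d] for d in t1.domain_ids]].astype(float),
            t1, params, genome_id=g,
        )
        run.step1[g] = r1
        if r1.predicted == "anaerobe":
            run.predictions[g] = "anaerobe"
            if store_tables:
                run.fold_tables[g] = (t1,)
            continue
        train2 = step2_base.drop_genomes([g])
        t2 = _fold_table(train2, labels, STEP2_SCHEME, selection_params, g2)
        r2 = posterior(
            row[[pos[d] for d in t2.domain_ids]].astype(float),
            t2, params, genome_id=g,
        )
        run.step2[g] = r2
        run.predictions[g] = r2.predicted
        if store_tables:
            run.fold_tables[g] = (t1, t2)
        if (i + 1) % 50 == 0:
            logger.info("two-step LOOCV: %d/%d folds done", i + 1, matrix.n_genomes)
    return run
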