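"""End-to-end orchestration: instrument selection through mediation.

The analysis design is three sequential MR stages: (1) exposure panel ->
outcome with panel-wise FDR; (2) mediator panel -> outcome with FDR plus
Steiger-direction and Egger/IVW sign-consistency exclusions; (3) for each
surviving (exposure, mediator) pair, exposure -> mediator MR and the
product-of-coefficients mediation decomposition.  Significance thresholds
for instrument selection are role-specific: molecular exposure panels use
p < 5e-6, immune-cell mediator panels p < 1e-5, diseases-as-exposures
p < 5e-8 (escalation to 5e-6 when instruments are scarce is an explicit
opt-in, never automatic).

Every bootstrap/simulation seed is derived deterministically from the
config seed and the trait pair, so re-running a configuration reproduces
byte-identical result tables.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .harmonize import HarmonizedPairs, harmonize, HarmonizationError
from .instruments import EmptyInstrumentsError, InstrumentSet, LdMatrix, select_instruments
from .mediation_fdr import build_result_table, mediation_effects
from .sensitivity import SensitivityReport, sensitivity_battery
from .sumstats_io import SumStats, read_rsid_list

logger = logging.getLogger(__name__)

MEDIATION_COLUMNS = ["exposure", "mediator", "outcome", "beta_total", "beta1", "beta2",
                     "indirect", "proportion_pct"]

DEFAULT_METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Thresholds, method list and seeds for one analysis run."""

    p_threshold_exposure: float = 5e-6
    p_threshold_mediator: float = 1e-5
    p_threshold_disease: float = 5e-8
    escalated_threshold: float = 5e-6
    allow_threshold_escalation: bool = False
    clump_kb: int = 10_000
    clump_r2: float = 0.001
    f_min: float = 10.0
    r2_method: str = "tstat"
    ivw_model: str = "auto"
    methods: tuple[str, ...] = DEFAULT_METHODS
    fdr_alpha: float = 0.05
    n_boot: int = 1000
    presso_nsim: int = 1000
    seed: int = est.DEFAULT_SEED
    exclusion: tuple[str, ...] = ()
    ld: Optional[LdMatrix] = None

    def threshold_for(self, role: str) -> float:
        thr = {
            "exposure": self.p_threshold_exposure,
            "mediator": self.p_threshold_mediator,
            "disease": self.p_threshold_disease,
        }
        if role not in thr:
            raise ValueError(f"unknown role {role!r}")
        return thr[role]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.pop("inputs", None)  # input file lists are consumed by the CLI
        excl_file = raw.pop("exclusion_file", None)
        if excl_file:
            raw["exclusion"] = tuple(read_rsid_list(excl_file))
        ld_file = raw.pop("ld_file", None)
        if ld_file:
            raw["ld"] = LdMatrix.read_tsv(ld_file)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        if "exclusion" in raw:
            raw["exclusion"] = tuple(raw["exclusion"])
        return cls(**raw)


def _derive_seed(seed: int, *labels: str) -> int:
    """Deterministic per-pair seed below 2^31, stable across runs."""
    return zlib.crc32("|".join([str(seed), *labels]).encode()) & 0x7FFFFFFF


@dataclass
class PairResult:
    """Everything computed for one exposure -> outcome MR pair."""

    exposure: str
    outcome: str
    estimates: list
    sensitivity: SensitivityReport
    pairs: HarmonizedPairs
    provenance: dict = field(default_factory=dict)

    def estimates_frame(self) -> pd.DataFrame:
        return est.estimates_to_frame(self.estimates, exposure=self.exposure, outcome=self.outcome)

    def sensitivity_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.sensitivity.to_row()])

    def primary(self):
        """The IVW row (or its single-SNP Wald fallback)."""
        for e in self.estimates:
            if e.method.startswith(("ivw", "wald")):
                return e
        raise LookupError("no IVW estimate in result")


def _run_estimators(pairs: HarmonizedPairs, cfg: AnalysisConfig, seed: int) -> list:
    out = []
    for method in cfg.methods:
        try:
            if method == "ivw":
                out.append(est.ivw(pairs, model=cfg.ivw_model))
            elif method == "egger":
                out.append(est.egger(pairs))
            elif method == "weighted_median":
                out.append(est.weighted_median(pairs, n_boot=cfg.n_boot, seed=seed))
            elif method == "simple_mode":
                out.append(est.mode_based(pairs, weighted=False, n_boot=cfg.n_boot, seed=seed))
            elif method == "weighted_mode":
                out.append(est.mode_based(pairs, weighted=True, n_boot=cfg.n_boot, seed=seed))
            else:
                raise ValueError(f"unknown method {method!r}")
        except est.InsufficientInstrumentsError as exc:
            logger.info("skipping %s for %s: %s", method, pairs.exposure_id, exc)
    return out


def run_mr_pair(
    exposure: SumStats,
    outcome: SumStats,
    cfg: AnalysisConfig,
    role: str = "exposure",
) -> PairResult:
    """Select instruments, harmonize, estimate, and run the full battery.

    Stage failures are re-raised as :class:`PipelineStageError` annotated
    with the stage name.  Deterministic given the config seed.
    """
    p_thr = cfg.threshold_for(role)
    try:
        inst = select_instruments(
            exposure, p_thr, exclusion=cfg.exclusion, ld=cfg.ld,
            window_kb=cfg.clump_kb, r2_max=cfg.clump_r2,
            f_min=cfg.f_min, r2_method=cfg.r2_method,
        )
    except EmptyInstrumentsError as exc:
        if cfg.allow_threshold_escalation and exc.stage == "p_filter" and cfg.escalated_threshold > p_thr:
            logger.warning(
                "%s: escalating p threshold %.2g -> %.2g (opt-in)",
                exposure.trait_id, p_thr, cfg.escalated_threshold,
            )
            try:
                inst = select_instruments(
                    exposure, cfg.escalated_threshold, exclusion=cfg.exclusion, ld=cfg.ld,
                    window_kb=cfg.clump_kb, r2_max=cfg.clump_r2,
                    f_min=cfg.f_min, r2_method=cfg.r2_method,
                )
            except EmptyInstrumentsError as exc2:
                raise PipelineStageError(f"instrument_selection:{exc2.stage}", str(exc2)) from exc2
        else:
            raise PipelineStageError(f"instrument_selection:{exc.stage}", str(exc)) from exc
    try:
        pairs = harmonize(inst, outcome)
    except HarmonizationError as exc:
        raise PipelineStageError("harmonization", str(exc)) from exc
    seed = _derive_seed(cfg.seed, exposure.trait_id, outcome.trait_id)
    estimates = _run_estimators(pairs, cfg, seed)
    sens = sensitivity_battery(pairs, presso_nsim=cfg.presso_nsim, seed=seed + 1)
    return PairResult(
        exposure=exposure.trait_id, outcome=outcome.trait_id,
        estimates=estimates, sensitivity=sens, pairs=pairs,
        provenance=dict(inst.provenance),
    )


def run_bidirectional(
    a: SumStats,
    b: SumStats,
    cfg: AnalysisConfig,
    role_a: str = "exposure",
    role_b: str = "disease",
) -> tuple[PairResult, PairResult]:
    """Run A -> B and B -> A with role-appropriate thresholds.

    Each direction carries its own Steiger directionality flag; downstream
    tables drop pairs whose presumed direction fails the test.
    """
    if a.trait_id == b.trait_id:
        logger.warning("bidirectional run with identical trait ids (%s): degenerate input", a.trait_id)
    forward = run_mr_pair(a, b, cfg, role=role_a)
    reverse = run_mr_pair(b, a, cfg, role=role_b)
    return forward, reverse


@dataclass
class MediationOutput:
    """Tables emitted by the three-step mediation pipeline."""

    mediation: pd.DataFrame
    step1: pd.DataFrame
    step2: pd.DataFrame
    step3: pd.DataFrame
    sensitivity: pd.DataFrame
    audit: pd.DataFrame
    failures: list[str] = field(default_factory=list)


def _panel_step(
    panel: Sequence[SumStats],
    outcome: SumStats,
    cfg: AnalysisConfig,
    role: str,
    family: str,
) -> tuple[pd.DataFrame, pd.DataFrame, list[PairResult], list[str]]:
    """Run one panel against one outcome, collecting estimate/sensitivity rows."""
    est_rows, sens_rows, results, failures = [], [], [], []
    for trait in panel:
        try:
            res = run_mr_pair(trait, outcome, cfg, role=role)
        except PipelineStageError as exc:
            logger.info("panel %s: %s skipped (%s)", family, trait.trait_id, exc)
            failures.append(f"{trait.trait_id}->{outcome.trait_id}: {exc}")
            continue
        frame = res.estimates_frame()
        frame["family"] = family
        est_rows.append(frame)
        sens_rows.append(res.sensitivity_frame())
        results.append(res)
    if not est_rows:
        return pd.DataFrame(), pd.DataFrame(), results, failures
    return pd.concat(est_rows, ignore_index=True), pd.concat(sens_rows, ignore_index=True), results, failures


def run_mediation_pipeline(
    exposures: Sequence[SumStats],
    mediators: Sequence[SumStats],
    outcome: SumStats,
    cfg: AnalysisConfig,
) -> MediationOutput:
    """Three-step mediation MR with panel-wise FDR at every step.

    Step 1 screens exposures against the outcome; Step 2 screens mediators
    against the outcome (excluding Steiger-inconsistent and Egger/IVW
    sign-disagreeing pairs); Step 3 runs each surviving exposure against each
    surviving mediator and, where significant after FDR over the surviving
    mediators, decomposes the effect by the product of coefficients.
    """
    if not len(exposures) or not len(mediators):
        raise ValueError("exposure and mediator panels must be non-empty")

    failures: list[str] = []
    est1, sens1, res1, f1 = _panel_step(exposures, outcome, cfg, "exposure", f"exposures|{outcome.trait_id}")
    failures += f1
    if est1.empty:
        logger.warning("mediation: no exposure produced estimates; empty mediation table")
        return MediationOutput(pd.DataFrame(columns=MEDIATION_COLUMNS), est1, pd.DataFrame(),
                               pd.DataFrame(), sens1, pd.DataFrame(), failures)
    step1, audit1 = build_result_table(est1, sens1, alpha=cfg.fdr_alpha)
    surv_exp = step1[step1["significant"]]["exposure"].tolist()

    est2, sens2, res2, f2 = _panel_step(mediators, outcome, cfg, "mediator", f"mediators|{outcome.trait_id}")
    failures += f2
    step2 = pd.DataFrame()
    audit2 = pd.DataFrame()
    surv_med: list[str] = []
    if not est2.empty:
        step2, audit2 = build_result_table(est2, sens2, alpha=cfg.fdr_alpha)
        keep2 = step2["significant"] & step2["egger_sign_agree"].fillna(True)
        surv_med = step2[keep2]["exposure"].tolist()

    med_rows = []
    est3_frames, sens3_frames = [], []
    if surv_exp and surv_med:
        med_lookup = {m.trait_id: m for m in mediators}
        beta_total = step1.set_index("exposure")["beta"]
        beta2 = step2.set_index("exposure")["beta"]
        for e_id in surv_exp:
            exp_stats = next(e for e in exposures if e.trait_id == e_id)
            # direction of step 3 is exposure -> mediator: the exposure trait is
            # instrumented and each mediator plays the outcome role.
            est3_e, sens3_e, _, f3e = _step3_exposure_to_mediators(
                exp_stats, [med_lookup[m] for m in surv_med], cfg
            )
            failures += f3e
            if est3_e.empty:
                continue
            step3_tab, audit3 = build_result_table(est3_e, sens3_e, alpha=cfg.fdr_alpha)
            est3_frames.append(step3_tab)
            sens3_frames.append(sens3_e)
            for row in step3_tab[step3_tab["significant"]].itertuples(index=False):
                m_id = row.outcome
                med = mediation_effects(
                    beta_total.loc[e_id], row.beta, beta2.loc[m_id],
                    exposure=e_id, mediator=m_id, outcome=outcome.trait_id,
                )
                med_rows.append(med.to_row())
    if not med_rows:
        logger.info("mediation: no surviving (exposure, mediator) pair; empty mediation table")
    mediation = pd.DataFrame(med_rows, columns=MEDIATION_COLUMNS)
    mediation = mediation.sort_values(["exposure", "mediator"]).reset_index(drop=True)

    step3 = pd.concat(est3_frames, ignore_index=True) if est3_frames else pd.DataFrame()
    sens_all = pd.concat(
        [f for f in (sens1, sens2, *sens3_frames) if len(f)], ignore_index=True
    ) if len(sens1) else sens1
    audit = pd.concat([f for f in (audit1, audit2) if len(f)], ignore_index=True) \
        if (len(audit1) or len(audit2)) else pd.DataFrame()
    return MediationOutput(mediation, step1, step2, step3, sens_all, audit, failures)


def _step3_exposure_to_mediators(
    exposure: SumStats,
    mediators: Sequence[SumStats],
    cfg: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[PairResult], list[str]]:
    """Step 3 helper: one exposure against each surviving mediator as outcome."""
    est_rows, sens_rows, results, failures = [], [], [], []
    family = f"{exposure.trait_id}|mediators"
    for med in mediators:
        try:
            res = run_mr_pair(exposure, med, cfg, role="exposure")
        except PipelineStageError as exc:
            failures.append(f"{exposure.trait_id}->{med.trait_id}: {exc}")
            continue
        frame = res.estimates_frame()
        frame["family"] = family
        est_rows.append(frame)
        sens_rows.append(res.sensitivity_frame())
        results.append(res)
    if not est_rows:
        return pd.DataFrame(), pd.DataFrame(), results, failures
    return pd.concat(est_rows, ignore_index=True), pd.concat(sens_rows, ignore_index=True), results, failures
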