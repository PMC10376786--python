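"""End-to-end orchestration: screen -> expand -> select -> train -> evaluate.

A run takes a feature table + clinical table (measured or simulated), builds
the second-order design for the chosen analyte block, pre-selects candidate
terms by OPLS-DA VIP, fits the constrained stepwise logistic panel, and
evaluates it by LOOCV/ROC.  Every artifact is written as CSV into the run
directory together with a manifest (config, seed, package version) that
suffices to reproduce the run; the whole pipeline is deterministic given the
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import hypergeom_enrich, read_edge_list, read_gmt
from .evaluate import EvaluationResult, evaluate_panel
from .io_tables import ClinicalTable, FeatureTable
from .logistic import LogisticFit, report_model, stepwise_select
from .opls import fit_oplsda, select_by_vip
from .products import expand_products
from .univariate import screen_markers

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_panel_selector"]

log = logging.getLogger("seropanel")


@dataclasses.dataclass
class PipelineConfig:
    output_dir: str | Path
    feature_path: str | Path | None = None
    feature_meta_path: str | Path | None = None
    clinical_path: str | Path | None = None
    pathway_path: str | Path | None = None
    edges_path: str | Path | None = None
    block: str = "protein"  # protein | lipid | both
    alpha: float = 0.05
    rho_min: float = 0.3
    vip_threshold: float = 1.0
    n_orth: int = 1
    constraint_phase: str = "forward_and_backward"
    max_terms: int = 12
    max_candidates: int | None = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block not in ("protein", "lipid", "both"):
            raise ValueError(f"invalid block {self.block!r}")
        if self.alpha <= 0 or self.vip_threshold < 0:
            raise ValueError("thresholds must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d


@dataclasses.dataclass
class PipelineResult:
    screening: pd.DataFrame
    candidates: list[str]
    fit: LogisticFit
    evaluation: EvaluationResult
    enrichment: pd.DataFrame | None
    run_dir: Path


def make_panel_selector(
    vip_threshold: float = 1.0,
    max_candidates: int | None = 30,
    max_terms: int = 4,
    alpha: float = 0.05,
    n_orth: int = 1,
):
    """Whole selection stage (OPLS-DA VIP -> constrained stepwise) as one
    callable ``selector(expanded_table, y) -> term list``.

    This is the unit that nested (selection-inside-fold) cross-validation
    re-runs per fold; the defaults keep a 49-sample training fold tractable
    (candidate cap, small panel cap) without touching the selection logic.
    """

    def selector(table, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_oplsda(table, y, n_orth=n_orth)
            cands = select_by_vip(model, threshold=vip_threshold)
            if max_candidates is not None:
                cands = cands[:max_candidates]
            fit, _ = stepwise_select(
                table, cands, y, alpha=alpha, max_terms=max_terms
            )
        return fit.term_names[1:]

    return selector


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    ft: FeatureTable | None = None,
    ct: ClinicalTable | None = None,
) -> PipelineResult:
    """Run all stages and write the artifact set into the run directory.

    Tables can be passed in memory (e.g. fresh from the simulator) or read
    from the configured paths.
    """
    from .io_tables import read_clinical_table, read_feature_table

    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "version": __version__,
        "status": "running",
    }
    try:
        if ft is None:
            if config.feature_path is None:
                raise ValueError("no feature table given")
            ft = read_feature_table(
                config.feature_path, meta_path=config.feature_meta_path
            )
        if ct is None:
            if config.clinical_path is None:
                raise ValueError("no clinical table given")
            ct = read_clinical_table(config.clinical_path)
        ct.check_companion(ft)
        y = ct.data.loc[ft.sample_ids, "group"].eq("metastatic").to_numpy(dtype=int)

        # 1. univariate screen (full table, both blocks)
        screening = screen_markers(ft, ct, alpha=config.alpha, rho_min=config.rho_min)
        screening.to_csv(run_dir / "screening.csv", index=False)
        log.info("screen: %d features, %d differential", len(screening),
                 int(screening["differential"].sum()))

        # 2. block restriction + product expansion
        if config.block == "both":
            block_ids = list(ft.feature_ids)
        else:
            block_ids = ft.features_of_class(config.block)
            if not block_ids:
                raise ValueError(f"no features of class {config.block!r}")
        expanded = expand_products(ft, include_squares=True, whitelist=block_ids)
        log.info("expand: %d base -> %d columns", len(block_ids), expanded.shape[1])

        # 3. OPLS-DA VIP pre-selection
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_oplsda(expanded, y, n_orth=config.n_orth)
        candidates = select_by_vip(model, threshold=config.vip_threshold)
        if config.max_candidates is not None:
            candidates = candidates[: config.max_candidates]
        vip_by_name = dict(zip(model.feature_names, model.vip))
        pd.DataFrame(
            {
                "feature": candidates,
                "VIP": [vip_by_name[c] for c in candidates],
                "rank": np.arange(1, len(candidates) + 1),
            }
        ).to_csv(run_dir / "candidates.csv", index=False)
        log.info("select: %d VIP>%g candidates", len(candidates), config.vip_threshold)

        # 4. constrained stepwise logistic panel
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, trace = stepwise_select(
                expanded,
                candidates,
                y,
                alpha=config.alpha,
                constraint_phase=config.constraint_phase,
                max_terms=config.max_terms,
            )
        report = report_model(fit)
        report.to_csv(run_dir / "model_report.csv", index=False)
        trace.to_frame().to_csv(run_dir / "trace.csv", index=False)
        log.info("train: %d terms selected, AIC %.2f", fit.k - 1, fit.aic)

        # 5. LOOCV evaluation
        panel_terms = fit.term_names[1:]
        evaluation = None
        if panel_terms:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                evaluation = evaluate_panel(panel_terms, expanded, y)
            evaluation.metrics_frame().to_csv(run_dir / "metrics.csv", index=False)
            evaluation.roc.to_csv(run_dir / "roc.csv", index=False)
        else:
            pd.DataFrame([{"auc": np.nan}]).to_csv(run_dir / "metrics.csv", index=False)
            pd.DataFrame(columns=["threshold", "sensitivity", "specificity"]).to_csv(
                run_dir / "roc.csv", index=False
            )

        # 6. pathway enrichment of screened markers (optional)
        enrich = None
        if config.pathway_path is not None:
            sets = read_gmt(config.pathway_path)
            edges = read_edge_list(config.edges_path) if config.edges_path else None
            selected = set(screening.loc[screening["differential"], "feature"])
            universe = set(ft.feature_ids)
            enrich = hypergeom_enrich(selected, sets, universe, edges=edges)
            enrich.to_csv(run_dir / "enrichment.csv", index=False)

        manifest["status"] = "ok"
        manifest["n_samples"], manifest["n_features"] = ft.shape
        manifest["n_candidates"] = len(candidates)
        manifest["panel_terms"] = panel_terms
        return PipelineResult(
            screening=screening,
            candidates=candidates,
            fit=fit,
            evaluation=evaluation,
            enrichment=enrich,
            run_dir=run_dir,
        )
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
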