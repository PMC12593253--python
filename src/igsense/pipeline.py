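"""End-to-end pipeline: design -> metrics -> simulation -> hierarchical
fit -> outlier screen -> outcome models, with a checksummed manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import hier, learner, outcomes, simulate, task
from .io import PipelineConfig, write_table

log = logging.getLogger("igsense")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, seed, files: list[Path], **extra) -> dict:
    return {
        "stage": name,
        "seed": seed,
        "files": [{"path": p.name, "sha256": _sha256(p)} for p in files],
        **extra,
    }


def _gam_summary(res) -> dict:
    return {
        "smooth_f": res.smooth_f,
        "smooth_edf": res.smooth_edf,
        "smooth_p": res.smooth_p,
        "adjusted_r2": res.adjusted_r2,
        "aic": res.aic,
        "n": res.n,
        "parametric": {
            name: {"estimate": t.estimate, "se": t.se, "t": t.tstat, "p": t.pvalue}
            for name, t in res.parametric.items()
        },
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    A stage failure aborts with the stage name while earlier outputs
    remain on disk. Re-running with the same config reproduces identical
    checksums for every stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": []}
    stage = "design"
    try:
        design = task.generate_design(seed=config.design_seed)
        design_path = outdir / "design.json"
        design_path.write_text(design.to_json())
        log.info("design: seed=%s, %d sequences", config.design_seed,
                 len(design.sequences))
        manifest["stages"].append(
            _stage("design", config.design_seed, [design_path],
                   n=len(design.sequences))
        )

        stage = "metrics"
        metrics = learner.compute_design_metrics(design, prior_count=config.alpha)
        metrics_path = write_table(metrics, outdir / "metrics.csv")
        manifest["stages"].append(
            _stage("metrics", None, [metrics_path], n=len(metrics),
                   alpha=config.alpha)
        )

        stage = "simulate"
        infants = simulate.simulate_infants(
            n=config.n_infants, seed=config.infant_seed
        )
        records = simulate.simulate_study(
            design, metrics, infants, seed=config.looking_seed
        )
        outc = simulate.simulate_outcomes(
            infants,
            simulate.OutcomeConfig(link=config.link),
            seed=config.outcome_seed,
        )
        followed = {p.infant_id for p in infants if p.followed_up and p.usable}
        infants_path = write_table(
            simulate.infants_to_frame(infants), outdir / "infants.csv"
        )
        looking_path = write_table(records, outdir / "looking.csv")
        outcomes_path = write_table(outc, outdir / "outcomes.csv")
        log.info(
            "simulate: %d infants recruited, %d with usable looking data, "
            "%d analyzable at follow-up",
            len(infants), records["infant_id"].nunique(), len(followed),
        )
        manifest["stages"].append(
            _stage(
                "simulate",
                [config.infant_seed, config.looking_seed, config.outcome_seed],
                [infants_path, looking_path, outcomes_path],
                n_recruited=len(infants),
                n_usable=int(records["infant_id"].nunique()),
                n_analyzable=len(followed),
            )
        )

        stage = "fit_hier"
        analyzable = records[records["infant_id"].isin(followed)]
        settings = hier.HierFitSettings(
            chains=config.chains,
            warmup_draws=config.warmup_draws,
            sampling_draws=config.sampling_draws,
            seed=config.fit_seed,
        )
        estimates, coefs, diag = hier.fit_hierarchical(analyzable, metrics, settings)
        sens = hier.estimates_to_frame(estimates)
        sens_path = write_table(sens, outdir / "sensitivity.csv")
        diag_path = outdir / "diagnostics.json"
        diag_path.write_text(
            json.dumps(
                {
                    "rhat_max": diag.rhat_max,
                    "ess_min": diag.ess_min,
                    "divergences": diag.divergences,
                    "converged": diag.converged,
                    "warnings": list(diag.warnings),
                    "population_coefficients": coefs.to_dict(orient="records"),
                },
                indent=2,
            )
        )
        if not diag.converged:
            log.warning("hierarchical fit: %s", "; ".join(diag.warnings))
        manifest["stages"].append(
            _stage("fit_hier", config.fit_seed, [sens_path, diag_path],
                   n=len(estimates))
        )

        stage = "outliers"
        kept, removed = outcomes.screen_sensitivity(sens, k_sd=config.outlier_k_sd)
        kept_path = write_table(kept, outdir / "sensitivity_screened.csv")
        log.info("outliers: %d kept, %d removed (%.1f-SD rule)",
                 len(kept), len(removed), config.outlier_k_sd)
        manifest["stages"].append(
            _stage("outliers", None, [kept_path], n_kept=len(kept),
                   n_removed=len(removed))
        )

        stage = "fit_outcome"
        outc_followed = outc[outc["infant_id"].isin(followed)]
        linear = outcomes.fit_linear_outcome(kept, outc_followed)
        gam = outcomes.fit_gam_outcome(kept, outc_followed)
        expo = outcomes.fit_exponential_outcome(kept, outc_followed)
        strata = outcomes.stratify_and_fit(kept, outc_followed)
        shares = outcomes.partial_r2(kept, outc_followed)
        sub = outcomes.fit_subindex_models(kept, outc_followed)
        results = {
            "n_analyzable": len(outc_followed),
            "n_after_outlier_screen": len(kept),
            "linear": {
                "aic": linear.aic,
                "terms": linear.table.to_dict(orient="records"),
            },
            "additive": _gam_summary(gam),
            "exponential": {
                "terms": expo.table.to_dict(orient="records"),
                "adjusted_r2": expo.table.attrs.get("adjusted_r2"),
            },
            "stratified": [
                {"group": s.group, "n": s.n, **_gam_summary(s.result)}
                for s in strata
            ],
            "partial_adjusted_r2": shares,
            "subindices": {
                "note": "exploratory; no multiplicity correction applied",
                **{k: _gam_summary(v) for k, v in sub.items()},
            },
        }
        results_path = outdir / "results.json"
        results_path.write_text(json.dumps(results, indent=2))
        manifest["stages"].append(
            _stage("fit_outcome", None, [results_path], n=len(kept))
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
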