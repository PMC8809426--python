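"""End-to-end orchestration of the two analyses.

``run_full_analysis`` ties the stages together: detection events,
face-capture contingency tables, agreement statistics (full, subsets,
singleton-adjusted), per-rater identity partitions, and the detection-rate
GLMM with backward selection.  Inputs default to the synthetic scenario
when no files are configured, so the full bundle is reproducible offline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import (
    KappaResult,
    PairingAttribute,
    SubsetMode,
    SubsetSpec,
    UndefinedKappaError,
    fleiss_kappa,
    fleiss_kappa_ci,
    rating_table_from_pairs,
    subset_kappa,
)
from .contingency import behavior_table, format_percent, pearson_chi2
from .events import assign_resolution_class, classify_night, group_events
from .glmm import ModelSpec, backward_select, diagnostics, type3_anova
from .io import (
    RunConfig,
    read_history,
    read_photos,
    read_ratings,
    read_sites,
    write_events,
    write_history,
    write_ratings,
)
from .ratings import count_individuals, partition_from_ratings, singleton_adjust
from .simulate import SimScenario, default_raters, simulate_detection_history, simulate_identities, simulate_ratings

logger = logging.getLogger("trapid")

DEFAULT_FULL_MODEL = ["deploy", "lure", "acd", "scrape", "acd:scrape", "deploy:acd"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ReportBundle:
    out_dir: Path
    files: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _kappa_row(result: KappaResult) -> dict:
    return {
        "subset": result.label,
        "n_pairings": result.n_pairings,
        "kappa": "" if result.kappa is None else round(result.kappa, 4),
        "ci_lower": "" if result.ci is None else round(result.ci[0], 4),
        "ci_upper": "" if result.ci is None else round(result.ci[1], 4),
        "note": "perfect/degenerate" if result.degenerate else ("empty" if result.empty else ""),
    }


def run_full_analysis(config: RunConfig, scenario: SimScenario | None = None) -> ReportBundle:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out_dir)
    stamp = f"trapid {__version__} config={config.config_hash()} seed={config.seed}"
    if scenario is None:
        scenario = SimScenario(seed=config.seed)
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    bundle.manifest = manifest

    def finish_stage(stage: str, path: Path) -> None:
        bundle.files[stage] = path
        manifest["stages"][stage] = {"file": path.name, "status": "ok"}
        _write_manifest(out_dir, manifest)

    # --- events stage -----------------------------------------------------
    try:
        if config.photos and config.sites:
            photos = read_photos(config.photos, timezone=config.timezone, strict=config.strict)
            sites = read_sites(config.sites, strict=config.strict)
        else:
            from .simulate import simulate_deployments, simulate_photo_stream

            sites = simulate_deployments(scenario)
            rated = simulate_identities(scenario)
            photos = simulate_photo_stream(rated, seed=config.seed)
        site_map = {s.site_id: s for s in sites}
        events = group_events(photos, gap_minutes=config.gap_minutes)
        for e in events:
            e.is_night = classify_night(e, site_map[e.site_id], config.twilight_threshold_deg)
        face_events = [e for e in events if e.face_resolution_px > 0]
        classed = {e.event_id: e for e in assign_resolution_class(face_events)} if face_events else {}
        events = [classed.get(e.event_id, e) for e in events]
        events_path = out_dir / "events.csv"
        write_events(events, events_path, header_comment=f"stage=events {stamp}")
        finish_stage("events", events_path)
    except Exception as exc:
        _write_manifest(out_dir, manifest)
        raise StageError("events", exc) from exc

    # --- contingency stage ------------------------------------------------
    try:
        rows = []
        face_acd = sum(1 for e in events if e.face_captured and site_map[e.site_id].has_acd)
        n_acd = sum(1 for e in events if site_map[e.site_id].has_acd)
        face_conv = sum(1 for e in events if e.face_captured and not site_map[e.site_id].has_acd)
        n_conv = len(events) - n_acd
        if min(n_acd, n_conv) > 0:
            from .contingency import ContingencyTable, DegenerateTableError

            table = ContingencyTable(
                counts=[[face_acd, n_acd - face_acd], [face_conv, n_conv - face_conv]],
                row_labels=["acd", "conventional"],
                col_labels=["face", "no_face"],
            )
            row = {
                "comparison": "face_capture_by_site_type",
                "acd_rate": format_percent(face_acd / n_acd),
                "conventional_rate": format_percent(face_conv / n_conv),
                "chi2": "", "df": "", "p": "",
            }
            try:
                test = pearson_chi2(table)
                row.update(chi2=round(test.statistic, 2), df=test.df, p=test.p_value)
            except DegenerateTableError:
                row["chi2"] = "degenerate"
            rows.append(row)
        behavior = behavior_table(events, site_map)
        contingency_path = out_dir / "contingency.csv"
        with open(contingency_path, "w") as fh:
            fh.write(f"# stage=contingency {stamp}\n")
            pd.DataFrame(rows).to_csv(fh, index=False)
            fh.write("\n# behavior x site-type counts\n")
            pd.DataFrame(
                behavior.counts, index=behavior.row_labels, columns=behavior.col_labels
            ).to_csv(fh)
        finish_stage("contingency", contingency_path)
    except Exception as exc:
        raise StageError("contingency", exc) from exc

    # --- agreement stage --------------------------------------------------
    try:
        if config.ratings:
            ratings = read_ratings(config.ratings, strict=config.strict)
            rated = None
        else:
            import dataclasses

            rated = simulate_identities(
                dataclasses.replace(scenario, n_events=scenario.n_rated_events)
            )
            ratings = simulate_ratings(rated, default_raters(), seed=config.seed)
            write_ratings(ratings, out_dir / "ratings.csv", header_comment=f"stage=simulate {stamp}")

        kappa_rows = []
        table = rating_table_from_pairs(ratings)
        try:
            kappa = fleiss_kappa(table)
            ci = fleiss_kappa_ci(table, level=config.kappa_level)
            kappa_rows.append(
                {"subset": "full", "n_pairings": table.n_subjects, "kappa": round(kappa, 4),
                 "ci_lower": round(ci[0], 4), "ci_upper": round(ci[1], 4), "note": ""}
            )
        except UndefinedKappaError:
            kappa_rows.append({"subset": "full", "n_pairings": table.n_subjects, "kappa": "",
                               "ci_lower": "", "ci_upper": "", "note": "perfect/degenerate"})

        adjustment = singleton_adjust(ratings)
        adj_table = rating_table_from_pairs(adjustment.adjusted)
        try:
            adj_kappa = fleiss_kappa(adj_table)
            adj_ci = fleiss_kappa_ci(adj_table, level=config.kappa_level)
            kappa_rows.append(
                {"subset": "singleton_adjusted", "n_pairings": adj_table.n_subjects,
                 "kappa": round(adj_kappa, 4), "ci_lower": round(adj_ci[0], 4),
                 "ci_upper": round(adj_ci[1], 4),
                 "note": f"singleton_fraction={adjustment.singleton_fraction:.3f}"}
            )
        except UndefinedKappaError:
            kappa_rows.append({"subset": "singleton_adjusted", "n_pairings": adj_table.n_subjects,
                               "kappa": "", "ci_lower": "", "ci_upper": "",
                               "note": "perfect/degenerate"})

        if rated is not None:
            event_map = {e.event_id: e for e in rated}
            for attribute in PairingAttribute:
                for mode in SubsetMode:
                    result = subset_kappa(ratings, event_map, SubsetSpec(attribute, mode),
                                          level=config.kappa_level)
                    kappa_rows.append(_kappa_row(result))

        kappa_path = out_dir / "kappa.csv"
        with open(kappa_path, "w") as fh:
            fh.write(f"# stage=agreement {stamp}\n")
            pd.DataFrame(kappa_rows).to_csv(fh, index=False)
        finish_stage("kappa", kappa_path)

        partition_rows = []
        for rater in ratings.raters:
            part = partition_from_ratings(ratings, rater)
            for i, comp in enumerate(part.components, start=1):
                partition_rows.append(
                    {"rater": rater, "individual": f"{rater}_I{i}",
                     "events": ";".join(sorted(comp)),
                     "contradictions": ";".join(f"{a}|{b}" for a, b in sorted(part.contradictions))
                     if i == 1 else ""}
                )
        counts = count_individuals(ratings)
        partitions_path = out_dir / "partitions.csv"
        with open(partitions_path, "w") as fh:
            fh.write(f"# stage=agreement {stamp}\n")
            fh.write(f"# individuals mean={counts.mean:.2f} min={counts.min} "
                     f"max={counts.max} sd={counts.sd:.3f}\n")
            pd.DataFrame(partition_rows).to_csv(fh, index=False)
        finish_stage("partitions", partitions_path)
    except Exception as exc:
        raise StageError("agreement", exc) from exc

    # --- glmm stage -------------------------------------------------------
    try:
        if config.history:
            history = read_history(config.history, strict=config.strict)
        else:
            import dataclasses

            glmm_scenario = scenario
            if not scenario.glmm_betas:
                glmm_scenario = dataclasses.replace(
                    scenario,
                    glmm_betas={"deploy": -0.3, "acd": 0.2, "scrape": 0.8, "acd:scrape": 0.5},
                )
            history, _ = simulate_detection_history(glmm_scenario)
            write_history(history, out_dir / "history.csv", header_comment=f"stage=simulate {stamp}")
        full_spec = ModelSpec(fixed_terms=list(DEFAULT_FULL_MODEL),
                              random_intercepts=["site", "season", "year"])
        spec, fit, trail = backward_select(history, full_spec, alpha=config.selection_alpha)
        selection_path = out_dir / "glmm_selection.csv"
        with open(selection_path, "w") as fh:
            fh.write(f"# stage=glmm {stamp}\n")
            pd.DataFrame(trail).to_csv(fh, index=False)
        finish_stage("glmm_selection", selection_path)

        anova = type3_anova(history, spec)
        coef = fit.coef_table()
        disp, zinf = diagnostics(fit, history)
        coef_path = out_dir / "glmm_coefficients.csv"
        with open(coef_path, "w") as fh:
            fh.write(f"# stage=glmm {stamp}\n")
            fh.write(f"# aic={fit.aic:.2f} loglik={fit.loglik:.2f} "
                     f"dispersion={disp:.3f} zero_inflation={zinf:.3f} "
                     f"re_sd={dict(zip(fit.re_names, fit.re_sd.round(4)))}\n")
            coef.to_csv(fh, index=False)
            fh.write("\n# type-III Wald tests (sum contrasts)\n")
            anova.to_csv(fh, index=False)
        finish_stage("glmm_coefficients", coef_path)
    except Exception as exc:
        raise StageError("glmm", exc) from exc

    manifest["status"] = "complete"
    _write_manifest(out_dir, manifest)
    return bundle


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
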