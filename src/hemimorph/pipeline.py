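"""Full-study orchestration: preprocess -> harmonize -> winsorize ->
univariate (contrast x family) -> multivariate (+ ILAE) -> cohort report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .cohort import cross_correlation_screen, match_report
from .harmonize import apply_harmonization, fit_harmonization
from .multivariate import FAMILIES, run_multivariate
from .preprocess import normalize, winsorize_stratified
from .types import CONTRASTS, MorphometricTable, Participant
from .univariate import results_frame, run_univariate_family

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    contrasts: tuple[str, ...] = CONTRASTS
    families: tuple[str, ...] = ("gross", "cxt", "csa", "cv", "subcortical")
    n_perm: int = 1000
    alpha: float = 0.05
    seed: int = 0
    winsor: tuple[float, float] = (5.0, 95.0)
    subgroup: str = "all"  # or "resection_only"
    do_normalize: bool = True
    do_harmonize: bool = True
    do_winsorize: bool = True
    counting: str = "strict"
    force_covariates: bool = False
    control_females: int | None = None
    control_n: int | None = None

    def validate(self) -> "RunConfig":
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 <= self.winsor[0] < self.winsor[1] <= 100):
            raise ValueError("bad winsor bounds")
        if self.subgroup not in ("all", "resection_only"):
            raise ValueError("subgroup must be 'all' or 'resection_only'")
        unknown = set(f.lower() for f in self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families {sorted(unknown)}")
        unknown = set(self.contrasts) - set(CONTRASTS)
        if unknown:
            raise ValueError(f"unknown contrasts {sorted(unknown)}")
        return self

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    config: dict
    provenance: dict
    univariate: dict[str, list[dict]] = field(default_factory=dict)
    multivariate: dict[str, dict] = field(default_factory=dict)
    cohort: list[dict] = field(default_factory=list)
    xcorr: dict[str, list[dict]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def univariate_frame(self, contrast: str, family: str) -> pd.DataFrame:
        return pd.DataFrame(self.univariate[f"{contrast}|{family}"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "provenance": self.provenance,
                    "univariate": self.univariate,
                    "multivariate": self.multivariate,
                    "cohort": self.cohort,
                    "xcorr": self.xcorr,
                    "skipped": self.skipped,
                },
                fh,
                indent=1,
                default=str,
            )

    @classmethod
    def from_json(cls, path) -> "StudyReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def filter_subgroup(
    table: MorphometricTable, participants: Sequence[Participant], subgroup: str
) -> tuple[MorphometricTable, list[Participant]]:
    if subgroup == "all":
        return table, list(participants)
    keep = [p for p in participants if p.group == "control" or p.surgery_kind == "resection"]
    ids = {p.id for p in keep}
    return table.subset(participant_id=ids), keep


def run_study(
    table: MorphometricTable,
    participants: Sequence[Participant],
    config: RunConfig | None = None,
) -> StudyReport:
    """Execute the configured study design; per-cell errors are recorded and
    the remaining cells proceed."""
    config = (config or RunConfig()).validate()
    table, participants = filter_subgroup(table, participants, config.subgroup)

    stages = []
    if config.do_normalize and not table.normalized:
        table = normalize(table)
        stages.append("normalize")
    if config.do_harmonize:
        model = fit_harmonization(table, participants)
        table = apply_harmonization(table, participants, model)
        stages.append("harmonize")
    if config.do_winsorize:
        table = winsorize_stratified(table, participants, *config.winsor)
        stages.append("winsorize")

    report = StudyReport(
        config=asdict(config),
        provenance={
            "config_hash": config.digest(),
            "seed": config.seed,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "stage_order": stages,
            "n_participants": len(participants),
        },
    )

    for contrast in config.contrasts:
        for family in config.families:
            key = f"{contrast}|{family}"
            try:
                results = run_univariate_family(
                    table,
                    participants,
                    contrast,
                    FAMILIES[family.lower()],
                    n_perm=config.n_perm,
                    seed=config.seed,
                    counting=config.counting,
                )
                report.univariate[key] = results_frame(results).to_dict("records")
            except Exception as exc:  # cell isolation by design
                log.exception("univariate cell %s failed", key)
                report.skipped[f"univariate:{key}"] = str(exc)

    outcomes = list(config.contrasts) + ["ilae_high_vs_low"]
    for outcome in outcomes:
        for family in config.families:
            key = f"{outcome}|{family}"
            try:
                sel = run_multivariate(
                    table,
                    participants,
                    outcome,
                    family,
                    alpha_entry=config.alpha,
                    force_covariates=config.force_covariates,
                )
                report.multivariate[key] = sel.to_dict()
            except Exception as exc:
                log.exception("multivariate cell %s failed", key)
                report.skipped[f"multivariate:{key}"] = str(exc)

    patients = [p for p in participants if p.group == "patient"]
    try:
        rep = match_report(
            patients, control_females=config.control_females, control_n=config.control_n
        )
        report.cohort = rep.comparisons
    except Exception as exc:
        report.skipped["cohort"] = str(exc)

    for subset in ("all", "lh", "rh"):
        try:
            xc = cross_correlation_screen(table, participants, subset=subset)
            report.xcorr[subset] = xc.to_dict("records")
        except Exception as exc:
            report.skipped[f"xcorr:{subset}"] = str(exc)

    return report


def render_summary(report: StudyReport, alpha: float | None = None) -> str:
    """Markdown at-a-glance summary; empty cells are marked 'n.s.'."""
    alpha = alpha if alpha is not None else report.config.get("alpha", 0.05)
    lines = ["# Study summary", ""]
    lines.append(f"Seed {report.provenance.get('seed')}, config {report.provenance.get('config_hash')}")
    lines.append("")
    lines.append("| contrast | family | univariate (BH-significant) | multivariate model |")
    lines.append("|---|---|---|---|")
    contrasts = report.config.get("contrasts", CONTRASTS)
    families = report.config.get("families", tuple(FAMILIES))
    for contrast in contrasts:
        for family in families:
            ukey = f"{contrast}|{family}"
            rows = report.univariate.get(ukey)
            if rows is None:
                uni = "skipped"
            else:
                sig = [r["region"] for r in rows if r["p_bh"] is not None and r["p_bh"] < alpha]
                uni = ", ".join(sig) if sig else "n.s."
            sel = report.multivariate.get(ukey)
            if sel is None:
                multi = "skipped"
            elif not sel["viable"]:
                multi = "n.s."
            else:
                multi = (
                    ", ".join(sel["selected"])
                    + f" (r2={sel['nagelkerke_r2']:.2f}, {sel['strength']})"
                )
            lines.append(f"| {contrast} | {family} | {uni} | {multi} |")
    for family in families:
        key = f"ilae_high_vs_low|{family}"
        sel = report.multivariate.get(key)
        if sel is None:
            continue
        multi = (
            ", ".join(sel["selected"]) + f" (r2={sel['nagelkerke_r2']:.2f}, {sel['strength']})"
            if sel["viable"]
            else "n.s."
        )
        lines.append(f"| ilae_high_vs_low | {family} | - | {multi} |")
    if report.skipped:
        lines += ["", "## Skipped cells", ""]
        for key, why in report.skipped.items():
            lines.append(f"- {key}: {why}")
    return "\n".join(lines) + "\n"


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Write report.json, per-cell CSVs, and summary.md under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_json(outdir / "report.json")
    for key, rows in report.univariate.items():
        name = key.replace("|", "_")
        pd.DataFrame(rows).to_csv(outdir / f"univariate_{name}.csv", index=False, lineterminator="\n")
    if report.cohort:
        pd.DataFrame(report.cohort).to_csv(outdir / "cohort_match.csv", index=False, lineterminator="\n")
    for subset, rows in report.xcorr.items():
        pd.DataFrame(rows).to_csv(outdir / f"xcorr_{subset}.csv", index=False, lineterminator="\n")
    (outdir / "summary.md").write_text(render_summary(report))
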