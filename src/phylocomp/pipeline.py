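"""End-to-end comparative analysis of gene-family size versus life history.

Loads a species trait table (gene counts for four immune gene families,
maximum lifespan, adult body weight) and two alternative time trees, then
runs the full analysis grid:

* per family x tree: Pearson correlation (count vs log lifespan),
  PGLS (log lifespan ~ count, fixed lambda), and independent-contrasts
  regression;
* per family x tree: body-mass-controlled PGLS with ML lambda
  (count ~ log lifespan + log body weight), reporting the lifespan
  coefficient;
* residual--residual correlations (both variables residualized on log body
  weight under PGLS);
* sensitivity refits (taxon exclusion, lifespan overrides, extra species).

The packaged default dataset (``data/synthetic_*``) is a synthetic stand-in
that emulates the design of the study this pipeline reproduces: 14 mammals,
one gene family strongly associated with lifespan and three control
families that are not.  See the module docstring of
:mod:`phylocomp.data` for details.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contrasts import felsenstein_contrasts
from .models import (
    PGLS,
    ContrastRegression,
    pearson_correlation,
    pgls_residualize,
)
from .tree import PhyloTree

__all__ = [
    "TRAIT_COLUMNS",
    "FAMILIES",
    "AnalysisConfig",
    "StudyReport",
    "load_trait_table",
    "align_table_and_tree",
    "run_family_grid",
    "run_mass_controlled",
    "run_residual_correlations",
    "run_sensitivity",
    "run_study",
    "render_report",
    "packaged_fixture_paths",
]

TRAIT_COLUMNS = [
    "cd33rsiglec_count",
    "klk_count",
    "tlr_count",
    "fcgr_count",
    "max_lifespan_years",
    "body_weight_grams",
]

#: report label -> trait-table column
FAMILIES = {
    "CD33rSIGLECs": "cd33rsiglec_count",
    "KLKs": "klk_count",
    "TLRs": "tlr_count",
    "IgG Fc receptors": "fcgr_count",
}

COUNT_COLUMNS = TRAIT_COLUMNS[:4]


def packaged_fixture_paths() -> dict[str, Path]:
    """Paths of the packaged synthetic demonstration dataset."""
    base = resources.files("phylocomp") / "data"
    return {
        "trait_table": Path(str(base / "synthetic_traits.csv")),
        "tree_I": Path(str(base / "synthetic_tree_I.nwk")),
        "tree_II": Path(str(base / "synthetic_tree_II.nwk")),
    }


# ---------------------------------------------------------------------
# Loading and validation


def load_trait_table(path) -> pd.DataFrame:
    """Load and validate a species trait table.

    Expects comma-separated text with header ``species`` plus the six value
    columns of :data:`TRAIT_COLUMNS`.  Species names are trimmed
    (case-preserved) and rows are sorted alphabetically by species.
    """
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("missing column 'species'")
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    df["species"] = df["species"].astype(str).str.strip()
    dups = df["species"][df["species"].duplicated()].tolist()
    if dups:
        raise ValueError(f"duplicate species rows: {sorted(set(dups))}")
    for col in TRAIT_COLUMNS:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value in column {col!r}, species "
                f"{bad['species'].iloc[0]!r}"
            )
        df[col] = pd.to_numeric(df[col])
    for col in COUNT_COLUMNS:
        bad = df[(df[col] < 0) | (df[col] != df[col].round())]
        if len(bad):
            raise ValueError(
                f"column {col!r} must hold non-negative integers; offending "
                f"species {bad['species'].iloc[0]!r}"
            )
        df[col] = df[col].astype(int)
    for col in ("max_lifespan_years", "body_weight_grams"):
        bad = df[df[col] <= 0]
        if len(bad):
            raise ValueError(
                f"column {col!r} must be strictly positive (log-transformable); "
                f"offending species {bad['species'].iloc[0]!r}"
            )
    return df.set_index("species").sort_index()


def align_table_and_tree(table: pd.DataFrame, tree: PhyloTree):
    """Prune ``tree`` to the table's species and order traits to match.

    Returns ``(table_in_tree_order, pruned_tree)``; raises if any species is
    absent from the tree.
    """
    species = set(table.index)
    missing = sorted(species - set(tree.leaf_labels))
    if missing:
        raise ValueError(f"species absent from tree: {missing}")
    pruned = tree if species == set(tree.leaf_labels) else tree.prune_to(species)
    return table.loc[pruned.leaf_labels], pruned


# ---------------------------------------------------------------------
# Configuration


@dataclass
class AnalysisConfig:
    """Everything a study run depends on, addressable from a flat text file."""

    trait_table: Path
    tree_paths: dict[str, Path]  # e.g. {"Tree I": ..., "Tree II": ...}
    families: list[str] = field(default_factory=lambda: list(FAMILIES))
    lambda_mode: float | str = 1.0  # fixed value for grid PGLS, or "ml"
    df_convention: str = "paper"
    log_base: float = 10.0
    exclude: list[str] = field(default_factory=list)
    lifespan_overrides: dict[str, float] = field(default_factory=dict)
    extra_table: Path | None = None
    extra_tree_paths: dict[str, Path] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def reproduction(cls, **overrides) -> "AnalysisConfig":
        """Config for the packaged synthetic demonstration dataset."""
        paths = packaged_fixture_paths()
        cfg = cls(
            trait_table=paths["trait_table"],
            tree_paths={"Tree I": paths["tree_I"], "Tree II": paths["tree_II"]},
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Parse a flat ``key = value`` config file.

        Recognized keys: ``trait_table``, ``tree_I``, ``tree_II``,
        ``families`` (comma list), ``lambda`` (number or ``ml``),
        ``df_convention``, ``log_base``, ``exclude`` (comma list),
        ``lifespan_override`` (``species=value`` items separated by ``;``),
        ``extra_table``, ``extra_tree_I``, ``extra_tree_II``, ``seed``.
        """
        kv: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = line.split("=", 1)
            kv[key.strip()] = val.strip()
        base = Path(path).parent

        def _p(v: str) -> Path:
            q = Path(v)
            return q if q.is_absolute() else base / q

        if "trait_table" not in kv:
            raise ValueError("config missing 'trait_table'")
        trees = {}
        for key, name in (("tree_I", "Tree I"), ("tree_II", "Tree II")):
            if key in kv:
                trees[name] = _p(kv[key])
        if not trees:
            raise ValueError("config must name at least one tree (tree_I/tree_II)")
        lam: float | str = kv.get("lambda", "1.0")
        if lam != "ml":
            lam = float(lam)
        overrides = {}
        if kv.get("lifespan_override"):
            for item in kv["lifespan_override"].split(";"):
                sp, v = item.split("=")
                overrides[sp.strip()] = float(v)
        extra_trees = {}
        for key, name in (("extra_tree_I", "Tree I"), ("extra_tree_II", "Tree II")):
            if key in kv:
                extra_trees[name] = _p(kv[key])
        cfg = cls(
            trait_table=_p(kv["trait_table"]),
            tree_paths=trees,
            lambda_mode=lam,
            df_convention=kv.get("df_convention", "paper"),
            log_base=float(kv.get("log_base", "10")),
            exclude=[s.strip() for s in kv.get("exclude", "").split(",") if s.strip()],
            lifespan_overrides=overrides,
            extra_table=_p(kv["extra_table"]) if "extra_table" in kv else None,
            extra_tree_paths=extra_trees,
            seed=int(kv.get("seed", "0")),
        )
        if kv.get("families"):
            fams = [f.strip() for f in kv["families"].split(",")]
            unknown = [f for f in fams if f not in FAMILIES]
            if unknown:
                raise ValueError(f"unknown families: {unknown}")
            cfg.families = fams
        for p in [cfg.trait_table, *cfg.tree_paths.values()]:
            if not Path(p).exists():
                raise ValueError(f"path does not exist: {p}")
        return cfg


# ---------------------------------------------------------------------
# Report


@dataclass
class StudyReport:
    """Structured results of a study run: one record per analysis cell."""

    cells: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def add(self, **cell) -> None:
        self.cells.append(cell)

    def section(self, name: str) -> list[dict]:
        return [c for c in self.cells if c.get("section") == name]

    def find(self, **match) -> list[dict]:
        return [
            c for c in self.cells if all(c.get(k) == v for k, v in match.items())
        ]

    def to_json(self) -> str:
        payload = {"provenance": self.provenance, "cells": self.cells}
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)

    def to_text(self) -> str:
        """Human-readable tables (p to 2 significant figures, t to 6 dp)."""
        lines = [f"phylocomp {self.provenance.get('version', '?')} study report", ""]
        for section in ("family_grid", "mass_controlled", "residual_correlation",
                        "sensitivity"):
            cells = self.section(section)
            if not cells:
                continue
            lines.append(f"## {section}")
            for c in cells:
                bits = [f"{c.get('tree', '-')}", f"{c.get('family', '-')}",
                        f"{c.get('method', '-')}"]
                if c.get("status") == "failed":
                    bits.append(f"FAILED: {c.get('reason')}")
                else:
                    for key in ("r2", "slope", "t", "p", "lambda", "r"):
                        if key in c and c[key] is not None:
                            v = c[key]
                            if key == "p":
                                bits.append(f"p={v:.2g}")
                            elif key == "t":
                                bits.append(f"t={v:.6f}")
                            else:
                                bits.append(f"{key}={v:.6g}")
                    if c.get("directive"):
                        bits.append(f"[{c['directive']}]")
                lines.append("  " + "  ".join(bits))
            lines.append("")
        return "\n".join(lines)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------
# Analysis sections


def _log(x, base: float):
    return np.log(x) / np.log(base)


def _load_inputs(config: AnalysisConfig):
    table = load_trait_table(config.trait_table)
    if config.extra_table is not None:
        extra = load_trait_table(config.extra_table)
        clash = set(table.index) & set(extra.index)
        if clash:
            raise ValueError(f"extra species already present: {sorted(clash)}")
        table = pd.concat([table, extra]).sort_index()
    for sp in config.exclude:
        if sp not in table.index:
            raise ValueError(f"exclude directive references unknown species {sp!r}")
    for sp in config.lifespan_overrides:
        if sp not in table.index:
            raise ValueError(f"lifespan override references unknown species {sp!r}")
    if config.lifespan_overrides:
        table = table.copy()
        for sp, v in config.lifespan_overrides.items():
            table.loc[sp, "max_lifespan_years"] = v
    if config.exclude:
        table = table.drop(index=config.exclude)
    tree_paths = dict(config.tree_paths)
    if config.extra_table is not None:
        if not config.extra_tree_paths:
            raise ValueError("extra species require extended trees")
        tree_paths = dict(config.extra_tree_paths)
    trees = {name: PhyloTree.from_file(p) for name, p in tree_paths.items()}
    return table, trees


def _grid_cell_pearson(table, family_col, log_base):
    cr = pearson_correlation(
        table[family_col], _log(table["max_lifespan_years"], log_base),
        df_convention="standard",
    )
    return {"r2": cr.r2, "r": cr.r, "t": cr.t, "df": cr.df, "p": cr.p}


def run_family_grid(config: AnalysisConfig, report: StudyReport | None = None,
                    directive: str | None = None) -> StudyReport:
    """Pearson / PGLS / contrast-regression grid over families and trees."""
    report = report if report is not None else StudyReport()
    table, trees = _load_inputs(config)
    section = "sensitivity" if directive else "family_grid"
    for tree_name, tree in trees.items():
        try:
            tab, ptree = align_table_and_tree(table, tree)
        except ValueError as exc:
            for fam in config.families:
                report.add(section=section, tree=tree_name, family=fam,
                           method="all", status="failed", reason=str(exc),
                           directive=directive)
            continue
        vcv = ptree.vcv()
        loglife = _log(tab["max_lifespan_years"], config.log_base)
        loglife.name = "log_lifespan"
        life_contrasts = felsenstein_contrasts(ptree, loglife.to_dict())
        for fam in config.families:
            col = FAMILIES[fam]
            count = tab[col].astype(float)
            base = {"section": section, "tree": tree_name, "family": fam,
                    "n": len(tab), "directive": directive}
            try:
                report.add(method="pearson", status="ok",
                           **base, **_grid_cell_pearson(tab, col, config.log_base))
            except ValueError as exc:
                report.add(method="pearson", status="failed", reason=str(exc), **base)
            try:
                fit = PGLS(loglife, count.to_frame("gene_count"), vcv).fit(
                    lam=config.lambda_mode, df_convention=config.df_convention
                )
                report.add(
                    method="pgls", status="ok",
                    slope=float(fit.params["gene_count"]),
                    se=float(fit.bse["gene_count"]),
                    t=float(fit.tvalues["gene_count"]),
                    df=fit.df_resid,
                    p=float(fit.pvalues["gene_count"]),
                    **{"lambda": fit.lambda_},
                    r2=fit.rsquared,
                    **base,
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                report.add(method="pgls", status="failed", reason=str(exc), **base)
            try:
                cc = felsenstein_contrasts(ptree, count.to_dict())
                fic = ContrastRegression(cc, life_contrasts).fit(
                    df_convention=config.df_convention
                )
                report.add(
                    method="fic", status="ok", slope=fic.slope, se=fic.bse,
                    t=fic.tvalue, df=fic.df_resid, p=fic.pvalue, **base,
                )
            except ValueError as exc:
                report.add(method="fic", status="failed", reason=str(exc), **base)
    return report


def run_mass_controlled(config: AnalysisConfig,
                        report: StudyReport | None = None) -> StudyReport:
    """PGLS with ML lambda: gene count ~ log lifespan + log body weight.

    Reports t and two-tailed p for the lifespan coefficient with the
    configured df convention.
    """
    report = report if report is not None else StudyReport()
    table, trees = _load_inputs(config)
    for tree_name, tree in trees.items():
        tab, ptree = align_table_and_tree(table, tree)
        vcv = ptree.vcv()
        X = pd.DataFrame(
            {
                "log_lifespan": _log(tab["max_lifespan_years"], config.log_base),
                "log_body_weight": _log(tab["body_weight_grams"], config.log_base),
            },
            index=tab.index,
        )
        for fam in config.families:
            base = {"section": "mass_controlled", "tree": tree_name,
                    "family": fam, "n": len(tab)}
            try:
                fit = PGLS(tab[FAMILIES[fam]].astype(float), X, vcv).fit(
                    lam="ml", df_convention=config.df_convention
                )
                report.add(
                    method="pgls_ml_lambda", status="ok",
                    slope=float(fit.params["log_lifespan"]),
                    se=float(fit.bse["log_lifespan"]),
                    t=float(fit.tvalues["log_lifespan"]),
                    df=fit.df_resid,
                    p=float(fit.pvalues["log_lifespan"]),
                    **{"lambda": fit.lambda_},
                    **base,
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                report.add(method="pgls_ml_lambda", status="failed",
                           reason=str(exc), **base)
    return report


def run_residual_correlations(config: AnalysisConfig,
                              report: StudyReport | None = None) -> StudyReport:
    """Residual--residual correlations after body-weight + phylogeny control.

    Both gene count and log lifespan are residualized on log body weight
    under PGLS(lambda = 1); the Pearson correlation of the residual pairs and
    the scatter coordinates are recorded (enough to redraw the residual
    plots).
    """
    report = report if report is not None else StudyReport()
    table, trees = _load_inputs(config)
    for tree_name, tree in trees.items():
        tab, ptree = align_table_and_tree(table, tree)
        vcv = ptree.vcv()
        logw = _log(tab["body_weight_grams"], config.log_base)
        logw.name = "log_body_weight"
        loglife = _log(tab["max_lifespan_years"], config.log_base)
        loglife.name = "log_lifespan"
        res_life = pgls_residualize(loglife, logw.to_frame(), vcv, lam=1.0)
        for fam in config.families:
            base = {"section": "residual_correlation", "tree": tree_name,
                    "family": fam, "n": len(tab)}
            try:
                res_count = pgls_residualize(
                    tab[FAMILIES[fam]].astype(float), logw.to_frame(), vcv, lam=1.0
                )
                cr = pearson_correlation(res_count, res_life)
                report.add(
                    method="residual_pearson", status="ok", r=cr.r, r2=cr.r2,
                    t=cr.t, df=cr.df, p=cr.p,
                    residual_count=[round(float(v), 12) for v in res_count],
                    residual_log_lifespan=[round(float(v), 12) for v in res_life],
                    species=list(res_count.index),
                    **base,
                )
            except ValueError as exc:
                report.add(method="residual_pearson", status="failed",
                           reason=str(exc), **base)
    return report


def run_sensitivity(config: AnalysisConfig, directives: list[dict],
                    report: StudyReport | None = None) -> StudyReport:
    """Refit the family grid under each sensitivity directive.

    A directive is a dict with any of the keys ``exclude`` (list of taxa),
    ``lifespan_overrides`` (species -> years), ``extra_table`` /
    ``extra_tree_paths`` (paths), and an optional ``label``.  The df rule of
    the configured convention is applied to the reduced/extended taxon count.
    """
    report = report if report is not None else StudyReport()
    for d in directives:
        label = d.get("label") or _directive_label(d)
        sub = AnalysisConfig(
            trait_table=config.trait_table,
            tree_paths=dict(config.tree_paths),
            families=d.get("families", list(config.families)),
            lambda_mode=config.lambda_mode,
            df_convention=config.df_convention,
            log_base=config.log_base,
            exclude=list(config.exclude) + list(d.get("exclude", [])),
            lifespan_overrides={**config.lifespan_overrides,
                                **d.get("lifespan_overrides", {})},
            extra_table=d.get("extra_table", config.extra_table),
            extra_tree_paths=d.get("extra_tree_paths", config.extra_tree_paths),
            seed=config.seed,
        )
        run_family_grid(sub, report=report, directive=label)
    return report


def _directive_label(d: dict) -> str:
    parts = []
    if d.get("exclude"):
        parts.append("exclude " + ",".join(d["exclude"]))
    if d.get("lifespan_overrides"):
        parts.append(
            "override " + ";".join(f"{k}={v}" for k, v in
                                   sorted(d["lifespan_overrides"].items()))
        )
    if d.get("extra_table"):
        parts.append("extra species")
    return "; ".join(parts) or "base"


# ---------------------------------------------------------------------
# Orchestration


def run_study(config: AnalysisConfig,
              sensitivity_directives: list[dict] | None = None) -> StudyReport:
    """The full analysis grid plus provenance."""
    report = StudyReport()
    report.provenance = {
        "version": __version__,
        "trait_table": str(config.trait_table),
        "trait_table_sha256": _sha256(config.trait_table),
        "trees": {n: str(p) for n, p in config.tree_paths.items()},
        "tree_sha256": {n: _sha256(p) for n, p in config.tree_paths.items()},
        "df_convention": config.df_convention,
        "lambda_mode": str(config.lambda_mode),
        "log_base": config.log_base,
        "seed": config.seed,
    }
    run_family_grid(config, report=report)
    run_mass_controlled(config, report=report)
    run_residual_correlations(config, report=report)
    if sensitivity_directives:
        run_sensitivity(config, sensitivity_directives, report=report)
    if not report.cells:
        raise ValueError("empty report")
    return report


def render_report(report: StudyReport, out_dir, formats=("json", "txt")) -> list[Path]:
    """Write the report; byte-stable across identical runs."""
    if not report.cells:
        raise ValueError("cannot render an empty report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        p = out_dir / "report.json"
        p.write_text(report.to_json() + "\n")
        written.append(p)
    if "txt" in formats:
        p = out_dir / "report.txt"
        p.write_text(report.to_text() + "\n")
        written.append(p)
    return written
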