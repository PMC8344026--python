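"""Prognostic-factor screening workflow for two-cause competing-risks data.

The workflow mirrors common registry practice for small dialysis cohorts:

1. categorize labs into handbook clinical bands;
2. univariate screen — one single-covariate competing-risks model per
   candidate variable per outcome cause (both causes always in the
   likelihood; the covariate enters only the outcome cause), retaining
   variables with Wald p below a liberal threshold (default 0.25, reported
   with 75% CIs);
3. collinearity check among the retained variables (pairwise association
   above a bound drops the later-listed variable);
4. multivariate model per outcome with the surviving variables (adjusted
   S-HRs, 90% CIs, significance at 0.10);
5. a cumulative-incidence table at whole years from the intercept-only fit.

Every stage is a plain function; :func:`run_pipeline` orchestrates them and
writes TSV tables, a markdown report and a run log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import model as mdl
from .cohort import CohortConfig, generate_cohort, read_cohort

__all__ = [
    "CategoryBin",
    "CategoryRule",
    "default_rules",
    "categorize",
    "dummy_columns",
    "univariate_screen",
    "collinearity_check",
    "multivariate_fit",
    "cumulative_incidence_table",
    "PipelineConfig",
    "ScreenReport",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

OUT_OF_RANGE = "out-of-range"


@dataclass(frozen=True)
class CategoryBin:
    """One labeled interval; closed ends by default, as the bands are printed."""

    label: str
    lo: float = -math.inf
    hi: float = math.inf
    lo_incl: bool = True
    hi_incl: bool = True

    def contains(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        above = x >= self.lo if self.lo_incl else x > self.lo
        below = x <= self.hi if self.hi_incl else x < self.hi
        return above & below


@dataclass(frozen=True)
class CategoryRule:
    """Ordered, non-overlapping bins for one variable plus its reference band."""

    variable: str
    bins: tuple[CategoryBin, ...]
    reference: str

    def __post_init__(self):
        labels = [b.label for b in self.bins]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{self.variable}: duplicate bin labels")
        if self.reference not in labels:
            raise ValueError(f"{self.variable}: reference {self.reference!r} not a bin label")
        for a, b in zip(self.bins, self.bins[1:]):
            if b.lo < a.hi or (b.lo == a.hi and a.hi_incl and b.lo_incl):
                raise ValueError(f"{self.variable}: bins overlap or are unordered")

    def assign(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full(x.shape, OUT_OF_RANGE, dtype=object)
        for b in self.bins:
            out[b.contains(x)] = b.label
        return out


def default_rules() -> tuple[CategoryRule, ...]:
    """Handbook clinical bands for the dialysis labs.

    Bands are closed intervals exactly as printed (lab values are reported
    to one decimal, so the printed bins are exhaustive); values at an open
    printed boundary ("<300" vs ">300" at exactly 300) go to the upper band.
    """
    B = CategoryBin
    return (
        CategoryRule("hemoglobin",
                     (B("<10", hi=10, hi_incl=False), B("10-12.5", 10, 12.5),
                      B(">12.5", lo=12.5, lo_incl=False)), reference="10-12.5"),
        CategoryRule("potassium",
                     (B("3.5-5", 3.5, 5.0), B(">5", lo=5.0, lo_incl=False)),
                     reference="3.5-5"),
        CategoryRule("alp",
                     (B("<300", hi=300, hi_incl=False), B(">300", lo=300)),
                     reference="<300"),
        CategoryRule("hba1c",
                     (B("<7", hi=7, hi_incl=False), B(">7", lo=7)),
                     reference="<7"),
        CategoryRule("calcium",
                     (B("<8.5", hi=8.5, hi_incl=False), B("8.5-9.5", 8.5, 9.5),
                      B(">9.5", lo=9.5, lo_incl=False)), reference="8.5-9.5"),
        CategoryRule("phosphorus",
                     (B("2.7-4.6", 2.7, 4.6), B("4.7-5.7", 4.7, 5.7),
                      B("5.8-6.8", 5.8, 6.8), B("6.9-9.9", 6.9, 9.9)),
                     reference="2.7-4.6"),
        CategoryRule("pth",
                     (B("<150", hi=150, hi_incl=False), B("150-600", 150, 600),
                      B(">600", lo=600, lo_incl=False)), reference="150-600"),
        CategoryRule("albumin",
                     (B("<4", hi=4, hi_incl=False), B("4-6.3", 4, 6.3)),
                     reference="<4"),
    )


def categorize(records: pd.DataFrame, rules) -> pd.DataFrame:
    """Add ``<variable>_cat`` label columns per the rules.

    Values outside every bin get the explicit ``out-of-range`` label with a
    logged warning; a rule naming an absent variable is an error.
    """
    out = records.copy()
    for rule in rules:
        if rule.variable not in out.columns:
            raise KeyError(f"variable {rule.variable!r} not present in records")
        labels = rule.assign(out[rule.variable])
        n_oor = int(np.sum(labels == OUT_OF_RANGE))
        if n_oor:
            logger.warning("%s: %d value(s) outside all bins labeled %r",
                           rule.variable, n_oor, OUT_OF_RANGE)
        out[f"{rule.variable}_cat"] = labels
    return out


def dummy_columns(records: pd.DataFrame, rule: CategoryRule) -> tuple[pd.DataFrame, list[str]]:
    """Reference-coded indicators for a categorized variable.

    Returns the frame with added ``{var}:{label}`` columns (reference and
    out-of-range levels excluded) and the list of added names.
    """
    col = f"{rule.variable}_cat"
    if col not in records.columns:
        records = categorize(records, [rule])
    out = records.copy()
    names = []
    for b in rule.bins:
        if b.label == rule.reference:
            continue
        nm = f"{rule.variable}:{b.label}"
        out[nm] = (out[col] == b.label).astype(float)
        names.append(nm)
    return out, names


# ---------------------------------------------------------------------------
# screening stages
# ---------------------------------------------------------------------------

def _variable_design(data: pd.DataFrame, variable: str, rules) -> tuple[pd.DataFrame, list[str]]:
    """Design columns for one candidate variable: itself if numeric-coded,
    else reference-coded indicators from its categorization rule."""
    rule = next((r for r in rules if r.variable == variable), None) if rules else None
    if rule is not None:
        return dummy_columns(data, rule)
    if variable not in data.columns:
        raise KeyError(f"variable {variable!r} not present")
    return data, [variable]


def univariate_screen(data: pd.DataFrame, variables, outcome: int,
                      threshold: float = 0.25, ci_level: float = 0.75,
                      rules=None, multistart: int = 3, seed: int = 0) -> pd.DataFrame:
    """Single-variable competing-risks screen for one outcome cause.

    Each candidate variable is fit in its own two-cause model in which the
    variable enters only the ``outcome`` cause; the competing cause is
    intercept-only.  A variable is retained when any of its coefficients has
    Wald p below ``threshold``.
    """
    if outcome not in (1, 2):
        raise ValueError("outcome must be 1 or 2")
    if not np.any(data["event"].to_numpy() == outcome):
        raise ValueError(f"no events of cause {outcome} in the data")
    pct = int(round(ci_level * 100))
    rows = []
    for var in variables:
        try:
            work, cols = _variable_design(data, var, rules)
            covs1 = tuple(cols) if outcome == 1 else ()
            covs2 = tuple(cols) if outcome == 2 else ()
            fit = mdl.fit_mle(work, covs1, covs2, multistart=multistart, seed=seed)
            if not fit.converged or fit.covariance is None:
                raise RuntimeError("fit did not converge")
            var_rows = []
            for c in cols:
                ci = mdl.wald_ci(fit, f"cause{outcome}:{c}", ci_level)
                level = c.split(":", 1)[1] if ":" in c else ""
                var_rows.append({
                    "variable": var, "level": level, "outcome": outcome,
                    "shr": ci.shr, f"ci{pct}_lo": ci.shr_lo,
                    f"ci{pct}_hi": ci.shr_hi, "p": ci.p,
                })
            retained = any(r["p"] < threshold for r in var_rows)
            for r in var_rows:
                r["retained"] = retained
                r["failed"] = False
            rows.extend(var_rows)
        except Exception as exc:  # noqa: BLE001 - contract: flag and continue
            logger.warning("univariate fit failed for %r (cause %d): %s", var, outcome, exc)
            rows.append({"variable": var, "level": "", "outcome": outcome,
                         "shr": np.nan, f"ci{pct}_lo": np.nan, f"ci{pct}_hi": np.nan,
                         "p": np.nan, "retained": False, "failed": True})
    return pd.DataFrame(rows, columns=["variable", "level", "outcome", "shr",
                                       f"ci{pct}_lo", f"ci{pct}_hi", "p",
                                       "retained", "failed"])


def _assoc(x: pd.Series, y: pd.Series) -> float:
    """Pairwise association on [0, 1]-ish scale for mixed variable types.

    numeric-numeric: |Pearson r|; numeric-categorical: correlation ratio
    (eta); categorical-categorical: Cramér's V (bias-uncorrected).
    """
    x_num = pd.api.types.is_numeric_dtype(x)
    y_num = pd.api.types.is_numeric_dtype(y)
    if x_num and y_num:
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(abs(np.corrcoef(x, y)[0, 1]))
    if x_num != y_num:
        num, cat = (x, y) if x_num else (y, x)
        grand = num.mean()
        ss_total = float(np.sum((num - grand) ** 2))
        if ss_total == 0:
            return 0.0
        ss_between = sum(len(g) * (g.mean() - grand) ** 2
                         for _, g in num.groupby(cat, observed=True))
        return float(math.sqrt(ss_between / ss_total))
    tab = pd.crosstab(x, y).to_numpy(dtype=float)
    n = tab.sum()
    if n == 0 or min(tab.shape) < 2:
        return 1.0 if tab.shape[0] == tab.shape[1] == 1 else 0.0
    expected = np.outer(tab.sum(1), tab.sum(0)) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.nansum((tab - expected) ** 2 / expected)
    k = min(tab.shape) - 1
    return float(math.sqrt(chi2 / (n * k)))


def collinearity_check(data: pd.DataFrame, variables, bound: float = 0.8,
                       rules=None) -> pd.DataFrame:
    """Pairs of candidate variables whose association exceeds ``bound``.

    Categorized variables are compared on their label columns.  Returns a
    frame with columns variable_a, variable_b, association, drop — ``drop``
    is the later-listed member of the pair.
    """
    variables = list(variables)
    if len(variables) < 2:
        return pd.DataFrame(columns=["variable_a", "variable_b", "association", "drop"])
    ruled = {r.variable for r in rules} if rules else set()
    series = {}
    work = categorize(data, [r for r in (rules or ()) if r.variable in variables])
    for v in variables:
        col = f"{v}_cat" if v in ruled else v
        series[v] = work[col]
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            r = _assoc(series[a], series[b])
            if r > bound:
                rows.append({"variable_a": a, "variable_b": b,
                             "association": r, "drop": b})
                logger.warning("collinear pair %s ~ %s (%.3f > %.2f): dropping %s",
                               a, b, r, bound, b)
    return pd.DataFrame(rows, columns=["variable_a", "variable_b", "association", "drop"])


def multivariate_fit(data: pd.DataFrame, retained1, retained2,
                     threshold: float = 0.10, ci_level: float = 0.90,
                     rules=None, multistart: int = 3, seed: int = 0):
    """Joint adjusted model per outcome cause over its retained variables.

    Returns ``(fit1, fit2, table)``: the per-cause ModelFits (None where the
    retained set is empty or the fit failed) and the adjusted-S-HR table
    with significance flags at ``threshold``.
    """
    retained1, retained2 = list(retained1), list(retained2)
    if not retained1 and not retained2:
        raise ValueError("retained set empty for both causes")
    pct = int(round(ci_level * 100))
    fits = {}
    rows = []
    for cause, retained in ((1, retained1), (2, retained2)):
        fits[cause] = None
        if not retained:
            continue
        work = data
        cols = []
        for v in retained:
            work, c = _variable_design(work, v, rules)
            cols.extend(c)
        if not cols:
            raise ValueError(f"cause {cause}: retained variables offer no estimable "
                             "contrast (reference-only categories)")
        try:
            fit = mdl.fit_mle(work, tuple(cols) if cause == 1 else (),
                              tuple(cols) if cause == 2 else (),
                              multistart=multistart, seed=seed)
            if not fit.converged or fit.covariance is None:
                raise RuntimeError("fit did not converge")
        except Exception as exc:  # noqa: BLE001
            logger.warning("multivariate fit failed for cause %d: %s", cause, exc)
            continue
        fits[cause] = fit
        for c in cols:
            ci = mdl.wald_ci(fit, f"cause{cause}:{c}", ci_level)
            var, _, level = c.partition(":")
            rows.append({
                "variable": var, "level": level, "outcome": cause,
                "adj_shr": ci.shr, f"ci{pct}_lo": ci.shr_lo,
                f"ci{pct}_hi": ci.shr_hi, "p": ci.p,
                "significant": ci.p < threshold,
            })
    table = pd.DataFrame(rows, columns=["variable", "level", "outcome", "adj_shr",
                                        f"ci{pct}_lo", f"ci{pct}_hi", "p",
                                        "significant"])
    return fits[1], fits[2], table


def cumulative_incidence_table(data: pd.DataFrame, years=(1, 2, 3, 4),
                               multistart: int = 3, seed: int = 0) -> pd.DataFrame:
    """Model-based cumulative incidence (percent) of both causes at whole years."""
    if len(data) == 0:
        raise ValueError("data must be nonempty")
    fit = mdl.fit_mle(data, (), (), multistart=multistart, seed=seed)
    years = np.asarray(years, dtype=float)
    F1, F2 = mdl.cif_curve(fit, None, years)
    return pd.DataFrame({"year": years,
                         "death_pct": 100.0 * np.atleast_1d(F1),
                         "transplant_pct": 100.0 * np.atleast_1d(F2)})


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

#: default candidate pool: every Table-style covariate the generator emits
DEFAULT_CONTINUOUS = ("age", "ferritin", "creatinine", "cholesterol",
                      "uric_acid", "sgot", "sgpt", "bilirubin")
DEFAULT_BINARY = ("male",)
DEFAULT_CATEGORIZED = ("hemoglobin", "potassium", "alp", "hba1c",
                       "calcium", "phosphorus", "pth", "albumin")


@dataclass
class PipelineConfig:
    """End-to-end screening-run recipe (input, thresholds, output paths)."""

    input_csv: str | None = None
    cohort: CohortConfig | None = None
    variables: tuple[str, ...] | None = None
    rules: tuple[CategoryRule, ...] = field(default_factory=default_rules)
    univariate_alpha: float = 0.25
    multivariate_alpha: float = 0.10
    ci_levels: tuple[float, float] = (0.75, 0.90)
    collinearity_bound: float = 0.8
    years: tuple[float, ...] = (1, 2, 3, 4)
    out_dir: str = "screen_output"
    seed: int = 0


@dataclass
class ScreenReport:
    """All artifacts of one pipeline run."""

    univariate: pd.DataFrame
    collinear: pd.DataFrame
    retained: dict
    multivariate: pd.DataFrame
    cif_table: pd.DataFrame | None
    notes: list[str]
    out_dir: Path | None = None


def run_pipeline(config: PipelineConfig) -> ScreenReport:
    """categorize -> univariate screen (both causes) -> collinearity ->
    multivariate -> cumulative incidence; writes TSVs, report.md, run.log."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gomprisk")
    root.addHandler(handler)
    notes: list[str] = []
    try:
        if config.input_csv is not None:
            data = read_cohort(config.input_csv)
            logger.info("loaded %d records from %s", len(data), config.input_csv)
        elif config.cohort is not None:
            data = generate_cohort(config.cohort, seed=config.seed)
            logger.info("simulated %d records (seed %d)", len(data), config.seed)
        else:
            raise ValueError("PipelineConfig needs input_csv or a cohort config")

        rules = tuple(r for r in config.rules if r.variable in data.columns)
        data = categorize(data, rules)

        if config.variables is not None:
            variables = list(config.variables)
        else:
            variables = [v for v in DEFAULT_CONTINUOUS + DEFAULT_BINARY
                         if v in data.columns]
            variables += [r.variable for r in rules
                          if r.variable in DEFAULT_CATEGORIZED]
        logger.info("candidate variables: %s", ", ".join(variables))

        lo, hi = config.ci_levels
        uni_frames = []
        retained: dict[int, list[str]] = {1: [], 2: []}
        for cause in (1, 2):
            n_ev = int((data["event"] == cause).sum())
            if n_ev == 0:
                msg = (f"no cause-{cause} events: univariate and multivariate "
                       f"tables for this outcome are omitted")
                notes.append(msg)
                logger.warning(msg)
                continue
            tab = univariate_screen(data, variables, cause,
                                    threshold=config.univariate_alpha,
                                    ci_level=lo, rules=rules, seed=config.seed)
            uni_frames.append(tab)
            retained[cause] = list(dict.fromkeys(
                tab.loc[tab["retained"], "variable"]))
        univariate = (pd.concat(uni_frames, ignore_index=True)
                      if uni_frames else pd.DataFrame())

        union = list(dict.fromkeys(retained[1] + retained[2]))
        collinear = collinearity_check(data, union, config.collinearity_bound,
                                       rules=rules)
        drops = set(collinear["drop"]) if len(collinear) else set()
        for cause in (1, 2):
            retained[cause] = [v for v in retained[cause] if v not in drops]
        if drops:
            notes.append("dropped for collinearity: " + ", ".join(sorted(drops)))

        if retained[1] or retained[2]:
            try:
                _, _, multivariate = multivariate_fit(
                    data, retained[1], retained[2],
                    threshold=config.multivariate_alpha, ci_level=hi,
                    rules=rules, seed=config.seed)
            except Exception as exc:  # noqa: BLE001
                notes.append(f"multivariate stage failed: {exc}")
                logger.warning("multivariate stage failed: %s", exc)
                multivariate = pd.DataFrame()
        else:
            notes.append("no variables retained by the univariate screen")
            multivariate = pd.DataFrame()

        cif_table = None
        try:
            if (data["event"] == 1).any() and (data["event"] == 2).any():
                cif_table = cumulative_incidence_table(data, config.years,
                                                       seed=config.seed)
            else:
                notes.append("cumulative-incidence table omitted: need events "
                             "of both causes")
        except Exception as exc:  # noqa: BLE001
            notes.append(f"cumulative-incidence stage failed: {exc}")
            logger.warning("cumulative-incidence stage failed: %s", exc)

        univariate.to_csv(out_dir / "univariate.tsv", sep="\t", index=False)
        collinear.to_csv(out_dir / "collinearity.tsv", sep="\t", index=False)
        multivariate.to_csv(out_dir / "multivariate.tsv", sep="\t", index=False)
        if cif_table is not None:
            cif_table.to_csv(out_dir / "cumulative_incidence.tsv", sep="\t",
                             index=False)
        report = ScreenReport(univariate=univariate, collinear=collinear,
                              retained=retained, multivariate=multivariate,
                              cif_table=cif_table, notes=notes, out_dir=out_dir)
        (out_dir / "report.md").write_text(render_report(report, config))
        return report
    finally:
        root.removeHandler(handler)
        handler.close()


def _md_table(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    if df is None or len(df) == 0:
        return "_(empty)_\n"
    show = df.copy()
    for c in show.columns:
        if pd.api.types.is_float_dtype(show[c]):
            show[c] = show[c].map(lambda v: floatfmt.format(v) if pd.notna(v) else "")
    header = "| " + " | ".join(show.columns) + " |"
    sep = "|" + "|".join("---" for _ in show.columns) + "|"
    body = "\n".join("| " + " | ".join(str(v) for v in row) + " |"
                     for row in show.itertuples(index=False))
    return "\n".join([header, sep, body]) + "\n"


def _with_reference_rows(table: pd.DataFrame, rules, value_col: str) -> pd.DataFrame:
    """Insert S-HR = 1 reference-band rows under each categorized variable."""
    if len(table) == 0:
        return table
    by_rule = {r.variable: r.reference for r in rules}
    rows = []
    seen = set()
    for _, row in table.iterrows():
        var, outcome = row["variable"], row["outcome"]
        if var in by_rule and (var, outcome) not in seen:
            seen.add((var, outcome))
            ref = {c: "" for c in table.columns}
            ref.update({"variable": var, "level": by_rule[var] + " (ref)",
                        "outcome": outcome, value_col: "1"})
            rows.append(ref)
        rows.append({c: row[c] for c in table.columns})
    return pd.DataFrame(rows, columns=table.columns)


def render_report(report: ScreenReport, config: PipelineConfig) -> str:
    """Markdown summary of a screening run."""
    lo, hi = config.ci_levels
    parts = ["# Competing-risks prognostic-factor screen\n"]
    if report.cif_table is not None:
        parts.append("## Cumulative incidence (intercept-only model, %)\n")
        parts.append(_md_table(report.cif_table, "{:.1f}"))
    parts.append(f"\n## Univariate screen (S-HR, {int(lo*100)}% CI; "
                 f"retain p < {config.univariate_alpha})\n")
    parts.append(_md_table(_with_reference_rows(report.univariate, config.rules,
                                                "shr")))
    if len(report.collinear):
        parts.append("\n## Collinearity drops\n")
        parts.append(_md_table(report.collinear))
    parts.append(f"\n## Multivariate models (adjusted S-HR, {int(hi*100)}% CI; "
                 f"significant at p < {config.multivariate_alpha})\n")
    parts.append(_md_table(_with_reference_rows(report.multivariate, config.rules,
                                                "adj_shr")))
    if report.notes:
        parts.append("\n## Notes\n")
        parts.extend(f"- {n}\n" for n in report.notes)
    return "".join(parts)
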