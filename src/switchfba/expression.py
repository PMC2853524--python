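"""Integration of expression time series with predicted flux profiles.

Each enzyme-coding gene is matched to one reaction (the one with the largest
time-averaged |flux| among the reactions its GPR rules mention), its log2
expression profile is correlated with that reaction's predicted flux profile
(Pearson r), and genes are classified as correlated (r > 0.5), uncorrelated,
or anticorrelated (r < −0.5).  Genes whose matched flux is identically zero
(zero-flux screen) or constant (no correlation information) are excluded
from the correlation denominator, with the reason recorded.  The
essentiality screen partitions genes by whether their matched reaction
carries non-zero flux at every time point.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dynamic import FluxTimeSeries
from .errors import ConfigError, DataError
from .model import MetabolicModel, gene_reaction_map

ZERO_FLUX_TOL = 1e-9
DEFAULT_R_LOW, DEFAULT_R_HIGH = -0.5, 0.5
DEFAULT_LOW_EXPRESSION_CUTOFF = 5.0


@dataclass
class ExpressionMatrix:
    """Gene × time log2 expression values."""

    values: pd.DataFrame  # index = gene ids, columns = hours (float)
    control_rows: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.values = self.values.astype(float)
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()])
            raise DataError(f"duplicate gene ids: {dupes}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataError("expression values must be finite")
        self.values.columns = [float(c) for c in self.values.columns]
        unknown_controls = self.control_rows - set(self.values.index)
        if unknown_controls:
            raise DataError(f"control rows absent from matrix: {sorted(unknown_controls)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def times(self) -> np.ndarray:
        return np.array(self.values.columns, dtype=float)

    def profile(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)


_TIME_HEADER = re.compile(r"^[tT]?\s*([0-9]+(?:\.[0-9]+)?)\s*h?$")


def _parse_time_header(header: str) -> float:
    m = _TIME_HEADER.match(str(header).strip())
    if not m:
        raise DataError(f"cannot parse time from column header {header!r}")
    return float(m.group(1))


def read_expression(path, control_rows: Optional[set[str]] = None) -> ExpressionMatrix:
    """Read a genes × times TSV: first column gene id, headers encode hours
    (``20``, ``t20`` or ``20h``)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    times = [_parse_time_header(c) for c in df.columns]
    values = pd.DataFrame(index=df.index.astype(str), columns=times, dtype=float)
    for i, (gene, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            try:
                values.iloc[i, j] = float(cell)
            except (TypeError, ValueError):
                raise DataError(
                    f"non-numeric expression value {cell!r} at gene {gene!r}, "
                    f"column {df.columns[j]!r}"
                ) from None
    return ExpressionMatrix(values=values, control_rows=set(control_rows or ()))


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    out.columns = [f"t{c:g}" for c in out.columns]
    out.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# gene ↔ reaction matching
# ---------------------------------------------------------------------------

def match_genes(
    model: MetabolicModel,
    flux_ts: FluxTimeSeries,
    per_timepoint: bool = False,
) -> dict[str, str]:
    """Match every gene to exactly one reaction.

    A gene catalyzing several reactions is matched to the one with the
    maximum predicted flux, measured as the largest time-mean |flux| over the
    whole course (ties broken by lexicographic reaction id, so the matching
    is deterministic).  With ``per_timepoint`` the score is instead the mean
    of per-timepoint maxima — an alternative reading of "maximum predicted
    flux" — which changes nothing for single-reaction genes.

    Genes whose reactions all carry zero flux are still matched (to their
    lexicographically first reaction); the zero-flux screen flags them.
    """
    g2r = gene_reaction_map(model)
    mean_abs = flux_ts.flux_matrix.abs().mean(axis=1, skipna=True)
    matching: dict[str, str] = {}
    for gene, rxns in g2r.items():
        candidates = sorted(r for r in rxns if r in flux_ts.flux_matrix.index)
        if not candidates:
            continue
        if per_timepoint and len(candidates) > 1:
            sub = flux_ts.flux_matrix.loc[candidates].abs()
            best = sub.idxmax(axis=0).mode().sort_values().iloc[0]
        else:
            best, best_score = candidates[0], -1.0
            for rid in candidates:
                score = float(mean_abs.loc[rid])
                if score > best_score:
                    best, best_score = rid, score
        matching[gene] = best
    return matching


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class GeneFluxProfile:
    gene: str
    matched_reaction: str
    flux_profile: np.ndarray
    expression_profile: Optional[np.ndarray]
    r: Optional[float] = None
    excluded: Optional[str] = None  # reason: zero_flux / constant_flux / ...
    cls: Optional[str] = None


@dataclass
class ClassCounts:
    counts: dict[str, int]
    fractions: dict[str, float]
    n_classified: int
    n_excluded: int


@dataclass
class CorrelationReport:
    profiles: list[GeneFluxProfile]
    thresholds: tuple[float, float] = (DEFAULT_R_LOW, DEFAULT_R_HIGH)
    class_counts: Optional[ClassCounts] = None

    def profile(self, gene: str) -> GeneFluxProfile:
        return next(p for p in self.profiles if p.gene == gene)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": p.gene,
                    "reaction": p.matched_reaction,
                    "r": np.nan if p.r is None else p.r,
                    "class": p.cls or "",
                    "excluded_reason": p.excluded or "",
                }
                for p in self.profiles
            ]
        )


def _align_times(
    flux_times: np.ndarray, expr_times: np.ndarray, max_gap: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pair expression times with the nearest flux time within ``max_gap`` h.

    Returns index arrays (into flux times, into expression times).  Expression
    times with no flux time within the gap are dropped with a warning.
    """
    fi, ei = [], []
    used = set()
    for j, t in enumerate(expr_times):
        k = int(np.argmin(np.abs(flux_times - t)))
        if abs(flux_times[k] - t) <= max_gap and k not in used:
            fi.append(k)
            ei.append(j)
            used.add(k)
    dropped = len(expr_times) - len(ei)
    if dropped:
        warnings.warn(
            f"{dropped} expression time points have no flux time within "
            f"{max_gap} h and were dropped",
            stacklevel=2,
        )
    if not ei:
        raise DataError("no overlapping time points between flux and expression")
    return np.array(fi), np.array(ei)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def correlate(
    flux_ts: FluxTimeSeries,
    expr: ExpressionMatrix,
    matching: dict[str, str],
    zero_tol: float = ZERO_FLUX_TOL,
    max_time_gap: float = 1.0,
) -> CorrelationReport:
    """Pearson correlation of each gene's expression vs its matched flux.

    Exclusions mirror the screening order of the analysis: genes whose
    matched reaction never carries flux are excluded as ``zero_flux``; genes
    with non-zero but constant flux (zero standard deviation — typically
    maintenance) as ``constant_flux``; constant expression profiles as
    ``constant_expression``.  Excluded genes carry no r and are not part of
    the classification denominator.
    """
    fi, ei = _align_times(flux_ts.times, expr.times, max_time_gap)
    profiles = []
    for gene in expr.genes:
        if gene not in matching:
            continue
        rid = matching[gene]
        flux = flux_ts.flux_profile(rid)[fi]
        expr_prof = expr.profile(gene)[ei]
        p = GeneFluxProfile(gene, rid, flux, expr_prof)
        if np.all(np.abs(flux[np.isfinite(flux)]) <= zero_tol):
            p.excluded = "zero_flux"
        elif np.nanstd(flux) == 0:
            p.excluded = "constant_flux"
        elif np.std(expr_prof) == 0:
            p.excluded = "constant_expression"
        else:
            ok = np.isfinite(flux)
            p.r = _pearson(flux[ok], expr_prof[ok])
        profiles.append(p)
    return CorrelationReport(profiles=profiles)


def classify(
    report: CorrelationReport,
    low: float = DEFAULT_R_LOW,
    high: float = DEFAULT_R_HIGH,
) -> ClassCounts:
    """Label non-excluded genes: correlated (r > high), anticorrelated
    (r < low), else uncorrelated.  Counts partition the non-excluded genes."""
    if low >= high:
        raise ConfigError(f"thresholds must satisfy low < high, got ({low}, {high})")
    counts = {"correlated": 0, "uncorrelated": 0, "anticorrelated": 0}
    n_excluded = 0
    for p in report.profiles:
        if p.excluded is not None:
            p.cls = None
            n_excluded += 1
            continue
        if p.r > high:
            p.cls = "correlated"
        elif p.r < low:
            p.cls = "anticorrelated"
        else:
            p.cls = "uncorrelated"
        counts[p.cls] += 1
    n = sum(counts.values())
    fractions = {k: (v / n if n else float("nan")) for k, v in counts.items()}
    report.thresholds = (low, high)
    report.class_counts = ClassCounts(
        counts=counts, fractions=fractions, n_classified=n, n_excluded=n_excluded
    )
    return report.class_counts


# ---------------------------------------------------------------------------
# zero-flux and essentiality screens
# ---------------------------------------------------------------------------

def zero_flux_genes(
    matching: dict[str, str],
    flux_ts: FluxTimeSeries,
    tol: float = ZERO_FLUX_TOL,
) -> set[str]:
    """Genes whose matched reaction carries no flux at any time point.

    Since matching picks the maximum-|flux| reaction, this equals the set of
    genes all of whose reactions are flux-free — genes the model deems unused
    for biomass production.  Expression dynamics in this set flag candidate
    model gaps.
    """
    out = set()
    for gene, rid in matching.items():
        flux = flux_ts.flux_profile(rid)
        flux = flux[np.isfinite(flux)]
        if len(flux) and np.all(np.abs(flux) <= tol):
            out.add(gene)
    return out


def essential_genes(
    matching: dict[str, str],
    flux_ts: FluxTimeSeries,
    tol: float = ZERO_FLUX_TOL,
) -> set[str]:
    """Genes with non-zero matched flux under *all* modeled conditions."""
    out = set()
    for gene, rid in matching.items():
        flux = flux_ts.flux_profile(rid)
        flux = flux[np.isfinite(flux)]
        if len(flux) and np.all(np.abs(flux) > tol):
            out.add(gene)
    return out


@dataclass
class EssentialitySummary:
    essential: set[str]
    non_essential: set[str]
    controls: set[str]
    medians: dict[str, Optional[float]]  # per-group median of per-gene medians
    low_expressed_essential: list[str]
    low_expressed_non_essential: list[str]
    low_expression_cutoff: float


def essential_expression_summary(
    flux_ts: FluxTimeSeries,
    expr: ExpressionMatrix,
    matching: dict[str, str],
    low_cutoff: float = DEFAULT_LOW_EXPRESSION_CUTOFF,
    tol: float = ZERO_FLUX_TOL,
) -> EssentialitySummary:
    """Compare expression of predicted-essential vs non-essential genes.

    Essential = non-zero matched flux at every time point; non-essential =
    the remaining matched genes; controls = the matrix's negative-control
    rows.  Each gene is summarized by its median log2 expression, and each
    group by the median of those.  An empty group's median is None (undefined),
    never 0.  Genes whose median expression falls below ``low_cutoff`` are
    listed per group — essential-but-unexpressed genes are candidates for
    redundant annotation or probe failure.
    """
    ess = essential_genes(matching, flux_ts, tol)
    matched = set(matching) & set(expr.genes)
    essential = ess & matched
    non_essential = matched - essential - expr.control_rows
    controls = expr.control_rows & set(expr.genes)

    def gene_median(g):
        return float(np.median(expr.profile(g)))

    def group_median(genes):
        return float(np.median([gene_median(g) for g in genes])) if genes else None

    return EssentialitySummary(
        essential=essential,
        non_essential=non_essential,
        controls=controls,
        medians={
            "essential": group_median(essential),
            "non_essential": group_median(non_essential),
            "controls": group_median(controls),
        },
        low_expressed_essential=sorted(
            g for g in essential if gene_median(g) < low_cutoff
        ),
        low_expressed_non_essential=sorted(
            g for g in non_essential if gene_median(g) < low_cutoff
        ),
        low_expression_cutoff=low_cutoff,
    )
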