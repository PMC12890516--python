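"""Single-myofiber proteomics: normalization, imputation, differential
abundance, restoration sets, and enrichment.

The workflow mirrors standard label-free / isobaric-tag practice:

* total-abundance normalization so every sample channel carries the same
  total signal (isobaric-tag designs);
* log2 transform, then removal of proteins too sparsely observed within any
  comparison group;
* mixed imputation: K-nearest-neighbour averaging where a group retains
  enough valid values, otherwise left-censored "MinProb" draws from a
  down-shifted, narrowed Gaussian (missingness in these data is abundance
  dependent - low-intensity proteins drop below the detection limit);
* per-protein two-sided t-tests with Benjamini-Hochberg FDR control and a
  fold-change gate;
* restoration-set logic partitioning disease-vs-control hits by whether a
  treatment contrast still finds them (maintained), no longer finds them
  (restored), finds them flipped (discordant), or finds new ones (emergent);
* hypergeometric over-representation tests against a term annotation, with a
  minimum-overlap rule and BH adjustment;
* PCA sample scores as a compact heterogeneity summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Protein x sample abundance matrix with a group map.

    ``values`` is a DataFrame (rows = proteins, columns = samples) with NaN
    marking missing observations; ``groups`` maps every sample to its group;
    ``scale`` is ``"raw"`` (linear intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    groups: pd.Series
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise InvalidInputError(f"unknown scale {self.scale!r}")
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise InvalidInputError(f"samples without a group: {missing}")
        self.groups = self.groups.loc[list(self.values.columns)]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def group_columns(self, group: str) -> list[str]:
        cols = [s for s, g in self.groups.items() if g == group]
        if not cols:
            raise InvalidInputError(f"no samples in group {group!r}")
        return cols

    @classmethod
    def from_files(
        cls, matrix_path: str, groups_path: str, scale: str = "log2"
    ) -> "AbundanceMatrix":
        """Load from a protein x sample TSV/CSV (blank cells = missing) and a
        two-column sample -> group map file."""
        sep = "," if str(matrix_path).endswith(".csv") else "\t"
        values = pd.read_csv(matrix_path, sep=sep, index_col=0)
        gsep = "," if str(groups_path).endswith(".csv") else "\t"
        gdf = pd.read_csv(groups_path, sep=gsep)
        if gdf.shape[1] < 2:
            raise InvalidInputError(
                f"group map {groups_path} needs columns sample_id, group"
            )
        groups = pd.Series(
            gdf.iloc[:, 1].values, index=gdf.iloc[:, 0].astype(str).values
        )
        values.columns = values.columns.astype(str)
        return cls(values=values, groups=groups, scale=scale)


# ---------------------------------------------------------------------------
# Normalization and filtering
# ---------------------------------------------------------------------------

def normalize_total_abundance(
    m: AbundanceMatrix, reference: str | float = "max"
) -> AbundanceMatrix:
    """Rescale each sample so all columns carry the same total abundance.

    ``reference`` anchors the common total: ``"max"`` (default) uses the
    largest column total, ``"mean"`` the average, or pass a number.  Ratios
    within each column are preserved.
    """
    if m.scale != "raw":
        raise InvalidInputError("total-abundance normalization expects raw scale")
    if (m.values < 0).any().any():
        raise InvalidInputError("raw intensities must be non-negative")
    totals = m.values.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise InvalidInputError(f"columns with zero total abundance: {bad}")
    if reference == "max":
        ref = float(totals.max())
    elif reference == "mean":
        ref = float(totals.mean())
    else:
        ref = float(reference)
    scaled = m.values * (ref / totals)
    return AbundanceMatrix(values=scaled, groups=m.groups, scale="raw")


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Log2-transform raw intensities (non-positive values become missing)."""
    if m.scale != "raw":
        raise InvalidInputError("matrix is already on log2 scale")
    vals = m.values.where(m.values > 0)
    return AbundanceMatrix(values=np.log2(vals), groups=m.groups, scale="log2")


def filter_by_missingness(
    m: AbundanceMatrix, max_missing_frac: float = 0.5
) -> tuple[AbundanceMatrix, list[str]]:
    """Drop proteins missing in more than ``max_missing_frac`` of the samples
    of any single group (strict inequality); returns (filtered, dropped ids).
    """
    if m.scale != "log2":
        raise InvalidInputError("missingness filter expects log2 scale")
    drop = pd.Series(False, index=m.values.index)
    for group in pd.unique(m.groups):
        cols = m.group_columns(group)
        frac = m.values[cols].isna().mean(axis=1)
        drop |= frac > max_missing_frac
    dropped = list(m.values.index[drop])
    kept = AbundanceMatrix(
        values=m.values.loc[~drop].copy(), groups=m.groups, scale="log2"
    )
    logger.info("missingness filter dropped %d/%d proteins", len(dropped), len(drop))
    return kept, dropped


# ---------------------------------------------------------------------------
# Mixed imputation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImputationReport:
    """Bookkeeping for one imputation run: which route handled each
    protein-group block and which cells were filled."""

    routes: pd.DataFrame  # proteins x groups: complete | knn | minprob
    imputed_mask: pd.DataFrame  # proteins x samples, True where filled


def mixed_impute(
    m: AbundanceMatrix,
    knn_valid_frac: float = 0.6,
    k: int = 3,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int | None = None,
    minprob_scope: str = "sample",
) -> tuple[AbundanceMatrix, ImputationReport]:
    """Impute missing log2 intensities with the mixed KNN / MinProb scheme.

    Per protein and per group: when at least ``knn_valid_frac`` of the group's
    samples are valid, missing entries are filled by k-nearest-neighbour
    averaging over proteins (neighbours by Euclidean distance on the group's
    jointly observed samples).  Remaining missing entries are drawn from a
    down-shifted Gaussian modeling left-censored values: for each sample with
    observed mean ``mu`` and standard deviation ``sd``, draws come from
    ``N(mu - shift*sd, (width*sd)^2)``.  Observed entries are never modified.

    ``minprob_scope`` selects whether ``mu``/``sd`` come from each sample
    column (default) or from the whole matrix (``"matrix"``).
    """
    if m.scale != "log2":
        raise InvalidInputError("imputation expects log2 scale")
    if minprob_scope not in ("sample", "matrix"):
        raise InvalidInputError(f"unknown minprob scope {minprob_scope!r}")
    values = m.values.copy()
    pre_missing = values.isna()
    n_proteins = len(values)
    routes = pd.DataFrame(
        "complete", index=values.index, columns=list(pd.unique(m.groups))
    )
    if k > n_proteins - 1:
        logger.warning(
            "k=%d exceeds the available neighbour pool (%d); using all",
            k, max(n_proteins - 1, 1),
        )
        k = max(min(k, n_proteins - 1), 1)

    for group in pd.unique(m.groups):
        cols = m.group_columns(group)
        block = values[cols]
        valid_frac = 1.0 - block.isna().mean(axis=1)
        has_missing = block.isna().any(axis=1)
        knn_rows = (valid_frac >= knn_valid_frac) & has_missing
        routes.loc[has_missing & ~knn_rows, group] = "minprob"
        routes.loc[knn_rows, group] = "knn"
        if knn_rows.any():
            imputer = KNNImputer(
                n_neighbors=k, weights="uniform", keep_empty_features=True
            )
            filled = pd.DataFrame(
                imputer.fit_transform(block.to_numpy()),
                index=block.index,
                columns=cols,
            )
            for col in cols:
                fill_idx = block.index[knn_rows & block[col].isna()]
                values.loc[fill_idx, col] = filled.loc[fill_idx, col]

    # MinProb for everything still missing, sample by sample
    rng = np.random.default_rng(seed)
    if minprob_scope == "matrix":
        obs = m.values.to_numpy()
        mu_all = float(np.nanmean(obs))
        sd_all = float(np.nanstd(obs, ddof=1))
    for col in values.columns:
        missing_idx = values.index[values[col].isna()]
        if len(missing_idx) == 0:
            continue
        if minprob_scope == "sample":
            observed = m.values[col].dropna()
            if observed.empty:
                raise InvalidInputError(f"sample {col!r} has no observed values")
            mu = float(observed.mean())
            sd = float(observed.std(ddof=1)) if len(observed) > 1 else 0.0
        else:
            mu, sd = mu_all, sd_all
        draws = rng.normal(mu - shift * sd, width * sd, size=len(missing_idx))
        values.loc[missing_idx, col] = draws

    report = ImputationReport(routes=routes, imputed_mask=pre_missing)
    out = AbundanceMatrix(values=values, groups=m.groups, scale="log2")
    return out, report


# ---------------------------------------------------------------------------
# Differential abundance
# ---------------------------------------------------------------------------

def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_abundance(
    m: AbundanceMatrix,
    case: str,
    control: str,
    alpha: float = 0.05,
    fc: float = 2.0,
    use_adjusted: bool = True,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-protein two-sided t-tests between two groups with an FDR and
    fold-change gate.

    ``log2fc`` is mean(case) - mean(control); a protein is ``significant``
    when its (BH-adjusted, or raw when ``use_adjusted`` is False) p-value is
    <= ``alpha`` AND ``|log2fc| >= log2(fc)``.  At ``fc=1`` the fold-change
    gate is inactive.  Requires complete data and n >= 2 in both groups.
    """
    case_cols = m.group_columns(case)
    ctrl_cols = m.group_columns(control)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise InvalidInputError("each contrast group needs n >= 2 samples")
    if m.scale != "log2":
        raise InvalidInputError("differential abundance expects log2 scale")
    a = m.values[case_cols].to_numpy()
    b = m.values[ctrl_cols].to_numpy()
    if np.isnan(a).any() or np.isnan(b).any():
        raise InvalidInputError(
            "contrast groups contain missing values; impute first"
        )
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    tstat, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    # constant identical rows yield 0/0; no evidence of change
    degenerate = ~np.isfinite(tstat)
    tstat = np.where(degenerate, 0.0, tstat)
    p = np.where(degenerate, 1.0, p)
    q = bh_adjust(p)
    gate_p = q if use_adjusted else p
    significant = (gate_p <= alpha) & (np.abs(log2fc) >= np.log2(fc))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": tstat,
            "p": p,
            "q": q,
            "significant": significant,
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=m.values.index,
    )


# ---------------------------------------------------------------------------
# Restoration sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RestorationSets:
    """Partition of differential proteins across two contrasts.

    ``maintained``: significant in both contrasts with the same direction;
    ``restored``: significant only against the untreated contrast;
    ``emergent``: significant only against the treated contrast;
    ``discordant``: significant in both with opposite directions.
    """

    maintained: frozenset
    restored: frozenset
    emergent: frozenset
    discordant: frozenset

    @property
    def counts(self) -> dict[str, int]:
        return {
            "maintained": len(self.maintained),
            "restored": len(self.restored),
            "emergent": len(self.emergent),
            "discordant": len(self.discordant),
        }


def restoration_sets(
    diff_untreated: pd.DataFrame,
    diff_treated: pd.DataFrame,
    direction: str = "both",
) -> RestorationSets:
    """Classify hits of a disease contrast by their fate under treatment.

    Both inputs are :func:`differential_abundance` tables computed against the
    same reference group.  ``direction`` restricts the hit sets to down- or
    upregulated proteins before the set logic (``"both"`` keeps all hits).
    """
    if direction not in ("down", "up", "both"):
        raise InvalidInputError(f"unknown direction {direction!r}")
    uni_u = set(diff_untreated.index)
    uni_t = set(diff_treated.index)
    if not (uni_u & uni_t):
        raise InvalidInputError("contrasts share no proteins")

    def sig_set(diff: pd.DataFrame) -> set:
        sel = diff["significant"]
        if direction != "both":
            sel = sel & (diff["direction"] == direction)
        return set(diff.index[sel])

    sig_u_all = set(diff_untreated.index[diff_untreated["significant"]])
    sig_t_all = set(diff_treated.index[diff_treated["significant"]])
    dir_u = diff_untreated["direction"]
    dir_t = diff_treated["direction"]
    a = sig_set(diff_untreated)
    b = sig_set(diff_treated)
    maintained = frozenset(
        p for p in a & sig_t_all if dir_u[p] == dir_t[p] and p in b
    )
    discordant = frozenset(p for p in a & sig_t_all if dir_u[p] != dir_t[p])
    restored = frozenset(a - sig_t_all)
    emergent = frozenset(b - sig_u_all)
    return RestorationSets(
        maintained=maintained,
        restored=restored,
        emergent=emergent,
        discordant=discordant,
    )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(
    hits: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    background: Iterable[str],
    min_targets: int = 5,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation tests per term.

    Terms are intersected with the background before testing; terms whose
    overlap with the hit list is below ``min_targets`` are excluded from
    testing (``passed_min_size`` False, adjusted p NaN).  BH adjustment runs
    across the tested terms only.
    """
    hits = set(hits)
    background = set(background)
    if not hits <= background:
        raise InvalidInputError("hit list is not a subset of the background")
    n_bg = len(background)
    n_hits = len(hits)
    rows = []
    for term_id in sorted(annotation):
        members = set(annotation[term_id]) & background
        overlap = len(members & hits)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(members), n_hits))
        rows.append(
            {
                "term_id": term_id,
                "term_size": len(members),
                "overlap": overlap,
                "p": min(p, 1.0),
                "passed_min_size": overlap >= min_targets,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = []
        return out
    out["q"] = np.nan
    tested = out["passed_min_size"]
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out.sort_values(["p", "term_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# PCA summary
# ---------------------------------------------------------------------------

def pca_scores(
    m: AbundanceMatrix,
    n_components: int | None = None,
    scale: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component sample scores of a complete matrix.

    Samples are observations (matrix transposed), centered per protein and
    optionally scaled to unit variance.  Returns (scores with one row per
    sample and columns PC1.., explained-variance fractions).
    """
    if m.values.isna().any().any():
        raise InvalidInputError("PCA requires a complete (imputed) matrix")
    x = m.values.to_numpy().T
    n_samples = x.shape[0]
    if n_samples < 2:
        raise InvalidInputError("PCA needs at least 2 samples")
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    max_comp = min(n_samples, x.shape[1])
    n_components = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    df = pd.DataFrame(scores, index=m.values.columns, columns=cols)
    df.insert(0, "group", m.groups.values)
    return df, pca.explained_variance_ratio_
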