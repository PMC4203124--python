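"""Marker handling and QTL-based prediction of model parameters.

Covers the genetic half of the pipeline: cleaning a multi-allelic genotype
matrix (rare-class masking, iterative random-forest imputation with an
out-of-bag error per marker, error-based filtering), structure-corrected
single-marker association scans with permutation-adjusted p-values,
linkage-disequilibrium blocking, backward-elimination multiple regression,
and the resulting additive marker models that map allele calls to a
parameter value (``V_sat`` in days, ``P_base`` in hours, ``TT_emhe`` in
modified degree-days).

Two fitted reference models for a European winter x spring bread-wheat
association panel ship with the package (see :func:`load_bundled_model`);
their leading terms are the major vernalization (*Vrn-A1*, *Vrn-B1*) and
photoperiod (*Ppd-D1*) gene markers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "ImputationReport",
    "AssociationRecord",
    "MarkerLinearModel",
    "mask_rare",
    "impute",
    "pfc_filter",
    "associate",
    "ld_blocks",
    "backward_eliminate",
    "major_gene_model",
    "predict_parameter",
    "load_bundled_model",
]


@dataclass
class GenotypeMatrix:
    """Genotypes x multi-allelic markers, calls as opaque class labels.

    ``calls`` is a string DataFrame (rows = genotypes, columns = markers)
    with ``NaN`` for missing; ``meta`` is indexed by marker with columns
    ``chromosome`` and ``n_missing_raw`` — the missing count frozen before
    any masking or imputation, used later to pick LD-block representatives.
    """

    calls: pd.DataFrame
    meta: pd.DataFrame

    @classmethod
    def from_calls(
        cls, calls: pd.DataFrame, chromosome: dict[str, str] | None = None
    ) -> "GenotypeMatrix":
        calls = calls.astype("object").where(pd.notna(calls), np.nan)
        meta = pd.DataFrame(index=calls.columns)
        meta["chromosome"] = pd.Series(chromosome or {}, dtype=object).reindex(
            calls.columns, fill_value="na"
        )
        meta["n_missing_raw"] = calls.isna().sum(axis=0).astype(int)
        return cls(calls, meta)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls.copy(), self.meta.copy())


def read_genotypes(path) -> GenotypeMatrix:
    """Genotype CSV: rows = genotypes, columns = markers, empty = missing."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return GenotypeMatrix.from_calls(df)


def write_genotypes(matrix: GenotypeMatrix, path) -> None:
    matrix.calls.rename_axis("genotype_id").to_csv(path)


# ----------------------------------------------------------- preprocessing


def mask_rare(matrix: GenotypeMatrix, min_freq: float = 0.05) -> GenotypeMatrix:
    """Set allele classes rarer than ``min_freq`` (among non-missing calls
    of each marker) to missing."""
    out = matrix.copy()
    for m in out.calls.columns:
        col = out.calls[m]
        counts = col.value_counts(dropna=True)
        n = counts.sum()
        if n == 0:
            continue
        rare = counts[counts / n < min_freq].index
        if len(rare):
            out.calls[m] = col.where(~col.isin(rare), np.nan)
    return out


@dataclass
class ImputationReport:
    """Out-of-bag error (PFC, proportion falsely classified) per imputed
    marker, plus convergence bookkeeping of the iterative refit."""

    pfc: dict[str, float] = field(default_factory=dict)
    iterations: int = 0
    converged: bool = False


def _one_hot(calls: pd.DataFrame) -> pd.DataFrame:
    z = pd.get_dummies(calls, prefix_sep="::", dtype=float)
    return z


def impute(
    matrix: GenotypeMatrix,
    seed: int = 0,
    n_trees: int = 100,
    max_iter: int = 10,
) -> tuple[GenotypeMatrix, ImputationReport]:
    """Iterative random-forest imputation of missing calls (missForest-style).

    Cells are seeded with the per-marker mode, then each marker with
    missing data is refit in turn as a classification of its observed
    calls on the one-hot encoding of all other markers; out-of-bag
    accuracy gives the per-marker PFC.  Iteration stops when the fraction
    of imputed cells that changed stops decreasing (the previous
    iteration's fill is kept) or at ``max_iter``.
    """
    from sklearn.ensemble import RandomForestClassifier

    if len(matrix.marker_ids) < 2:
        raise ValueError("imputation needs at least two markers")
    calls = matrix.calls.copy()
    miss = calls.isna()
    all_missing = [m for m in calls.columns if miss[m].all()]
    if all_missing:
        raise ValueError(f"markers missing in every genotype: {all_missing}")
    targets = [m for m in calls.columns if miss[m].any()]
    report = ImputationReport()
    if not targets:
        return matrix.copy(), report

    rng = np.random.default_rng(seed)
    # initial fill: per-marker modal class
    filled = calls.copy()
    for m in calls.columns:
        mode = calls[m].mode(dropna=True)
        filled.loc[miss[m], m] = mode.iloc[0]
    # fewest-missing first, the missForest visiting order
    targets.sort(key=lambda m: (int(miss[m].sum()), list(calls.columns).index(m)))

    prev_change = np.inf
    prev_filled = filled.copy()
    n_missing_cells = int(miss.values.sum())
    for it in range(1, max_iter + 1):
        before = filled.copy()
        Z = _one_hot(filled)
        for m in targets:
            other = Z.loc[:, ~Z.columns.str.startswith(f"{m}::")]
            y_obs = calls.loc[~miss[m], m].astype(str)
            X_obs = other.loc[~miss[m]]
            if y_obs.nunique() < 2:
                report.pfc[m] = 0.0
                filled.loc[miss[m], m] = y_obs.iloc[0]
                continue
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                oob_score=True,
                bootstrap=True,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # sparse OOB coverage warnings
                clf.fit(X_obs.values, y_obs.values)
                oob = clf.oob_score_
            report.pfc[m] = float(1.0 - oob)
            filled.loc[miss[m], m] = clf.predict(other.loc[miss[m]].values)
        changed = int((filled != before).values[miss.values].sum())
        change = changed / max(n_missing_cells, 1)
        report.iterations = it
        if change >= prev_change:
            filled = prev_filled  # keep the better previous iteration
            report.converged = True
            break
        if change == 0.0:
            report.converged = True
            break
        prev_change = change
        prev_filled = filled.copy()
    out = GenotypeMatrix(filled, matrix.meta.copy())
    return out, report


def pfc_filter(
    matrix: GenotypeMatrix, report: ImputationReport, max_pfc: float = 0.2
) -> GenotypeMatrix:
    """Drop markers whose imputation error is strictly above ``max_pfc``."""
    keep = [
        m for m in matrix.marker_ids if report.pfc.get(m, 0.0) <= max_pfc
    ]
    return GenotypeMatrix(matrix.calls[keep].copy(), matrix.meta.loc[keep].copy())


# ------------------------------------------------------------- association


@dataclass
class AssociationRecord:
    marker_id: str
    trait: str
    raw_p: float
    adjusted_p: float | None  # None when B = 0
    r2: float
    n: int


def _marker_design(col: pd.Series, rows: np.ndarray) -> np.ndarray | None:
    """Indicator columns (reference class dropped) for a marker restricted
    to ``rows``; None if monomorphic there."""
    vals = col.iloc[rows].astype(str)
    classes = sorted(vals.unique())
    if len(classes) < 2:
        return None
    return np.column_stack([(vals == c).to_numpy(float) for c in classes[1:]])


def associate(
    trait_values: pd.Series,
    matrix: GenotypeMatrix,
    structure: pd.DataFrame,
    trait: str = "trait",
    B: int = 1000,
    seed: int = 0,
) -> list[AssociationRecord]:
    """Single-marker association scan with structure covariates.

    For each marker, the trait is regressed on the marker's allele classes
    (categorical) plus the ancestral-group contributions; the marker term's
    partial F-test gives the raw p-value and its incremental sum of squares
    over the structure-only model gives ``r2``.  The four group
    contributions sum to one, so three of them enter alongside the
    intercept.  Adjusted p-values come from ``B`` permutations of the trait
    across genotypes (covariates fixed; scheme ``trait_shuffle``):
    ``(1 + #{perm F >= obs F}) / (B + 1)``.
    """
    gids = [g for g in matrix.genotype_ids if g in trait_values.index]
    gids = [g for g in gids if np.isfinite(trait_values[g])]
    y_full = trait_values.loc[gids].to_numpy(float)
    S = structure.loc[gids, ["g1", "g2", "g3"]].to_numpy(float)
    calls = matrix.calls.loc[gids]
    n_all = len(gids)

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n_all) for _ in range(B)]) if B else None

    records: list[AssociationRecord] = []
    for m in matrix.marker_ids:
        obs_rows = np.nonzero(calls[m].notna().to_numpy())[0]
        D = _marker_design(calls[m], obs_rows)
        if D is None:
            warnings.warn(
                f"marker {m!r} monomorphic after masking; skipped", stacklevel=2
            )
            continue
        y = y_full[obs_rows]
        n = len(y)
        Xr = np.column_stack([np.ones(n), S[obs_rows]])
        Xf = np.column_stack([Xr, D])
        df1 = D.shape[1]
        df2 = n - Xf.shape[1]
        if df2 <= 0:
            warnings.warn(f"marker {m!r}: not enough genotypes; skipped", stacklevel=2)
            continue
        Qr = np.eye(n) - Xr @ np.linalg.pinv(Xr)
        Qf = np.eye(n) - Xf @ np.linalg.pinv(Xf)

        def rss(Q, Y):
            R = Q @ Y
            return np.einsum("i...,i...->...", R, R)

        rss_r, rss_f = rss(Qr, y), rss(Qf, y)
        if rss_f <= 0:
            f_obs, raw_p = np.inf, 0.0
        else:
            f_obs = ((rss_r - rss_f) / df1) / (rss_f / df2)
            raw_p = float(stats.f.sf(f_obs, df1, df2))
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = float((rss_r - rss_f) / tss) if tss > 0 else 0.0
        adj = None
        if B:
            Yp = y_full[perms][:, obs_rows].T  # (n, B)
            rss_rp, rss_fp = rss(Qr, Yp), rss(Qf, Yp)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_perm = ((rss_rp - rss_fp) / df1) / (rss_fp / df2)
            adj = float((1 + np.sum(f_perm >= f_obs)) / (B + 1))
        records.append(AssociationRecord(m, trait, raw_p, adj, r2, n))
    return records


# --------------------------------------------------------------- LD blocks


def _indicator_frame(matrix: GenotypeMatrix) -> pd.DataFrame:
    z = pd.DataFrame(index=matrix.calls.index)
    for m in matrix.marker_ids:
        col = matrix.calls[m]
        for c in sorted(col.dropna().astype(str).unique()):
            ind = (col.astype(str) == c).astype(float)
            ind[col.isna()] = np.nan
            z[f"{m}::{c}"] = ind
    return z


def ld_blocks(
    matrix: GenotypeMatrix, r_threshold: float = 0.8
) -> tuple[list[list[str]], list[str]]:
    """Blocks of collinear markers and one representative per block.

    For multi-allelic markers the collinearity statistic ``r_LD`` is the
    maximum absolute correlation over all pairs of allele-class indicator
    columns (pairwise-complete).  Blocks are connected components of the
    ``r_LD >= r_threshold`` graph; the representative is the member with
    the fewest missing calls before imputation, ties broken by column
    order.
    """
    import networkx as nx

    markers = matrix.marker_ids
    z = _indicator_frame(matrix)
    corr = z.corr(min_periods=2).abs()
    owner = {c: c.split("::", 1)[0] for c in z.columns}
    g = nx.Graph()
    g.add_nodes_from(markers)
    cols = list(z.columns)
    for i, ci in enumerate(cols):
        for cj in cols[i + 1 :]:
            mi, mj = owner[ci], owner[cj]
            if mi == mj:
                continue
            r = corr.at[ci, cj]
            if np.isfinite(r) and r >= r_threshold:
                g.add_edge(mi, mj)
    order = {m: i for i, m in enumerate(markers)}
    blocks, reps = [], []
    comps = sorted(nx.connected_components(g), key=lambda c: min(order[m] for m in c))
    for comp in comps:
        block = sorted(comp, key=order.get)
        rep = min(block, key=lambda m: (int(matrix.meta.at[m, "n_missing_raw"]), order[m]))
        blocks.append(block)
        reps.append(rep)
    return blocks, reps


# ------------------------------------------------------------ linear model


@dataclass
class MarkerLinearModel:
    """Additive allele-effect model: intercept + sum of carried non-reference
    allele effects.  The reference allele of each term has implicit effect
    zero."""

    trait: str
    intercept: float
    terms: list[dict]  # {marker, reference, effects: {allele: coef}, chromosome?}
    r2_fit: float | None = None

    def markers(self) -> list[str]:
        return [t["marker"] for t in self.terms]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "trait": self.trait,
                    "intercept": self.intercept,
                    "terms": self.terms,
                    "r2_fit": self.r2_fit,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, source) -> "MarkerLinearModel":
        if hasattr(source, "read"):
            obj = json.load(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(obj["trait"], obj["intercept"], obj["terms"], obj.get("r2_fit"))


def predict_parameter(model: MarkerLinearModel, genotype_calls) -> float:
    """Predicted trait value for one genotype.

    ``genotype_calls`` maps marker id -> allele class; a missing or unknown
    call at any model marker is an error (never a silent zero).
    """
    value = model.intercept
    for term in model.terms:
        m = term["marker"]
        if m not in genotype_calls:
            raise KeyError(f"genotype has no call at model marker {m!r}")
        allele = genotype_calls[m]
        if allele is None or (isinstance(allele, float) and np.isnan(allele)):
            raise ValueError(f"missing call at model marker {m!r}")
        allele = str(allele)
        if allele == str(term["reference"]):
            continue
        effects = term["effects"]
        if allele not in effects:
            raise ValueError(
                f"unknown allele {allele!r} at marker {m!r} "
                f"(known: {sorted(effects)} + reference {term['reference']!r})"
            )
        value += effects[allele]
    return float(value)


def _fit_marker_ols(
    y: np.ndarray, designs: dict[str, tuple[np.ndarray, list[str], str]]
):
    """OLS of y on intercept + all marker indicator blocks; returns the
    coefficients, per-marker partial-F p-values and R^2."""
    n = len(y)
    cols = [np.ones(n)]
    spans: dict[str, slice] = {}
    pos = 1
    for m, (D, _, _) in designs.items():
        cols.append(D)
        spans[m] = slice(pos, pos + D.shape[1])
        pos += D.shape[1]
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss_f = float(resid @ resid)
    df2 = n - X.shape[1]
    pvals = {}
    for m in designs:
        keep = [j for j in range(X.shape[1]) if not (spans[m].start <= j < spans[m].stop)]
        Xr = X[:, keep]
        cr, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rr = y - Xr @ cr
        rss_r = float(rr @ rr)
        df1 = spans[m].stop - spans[m].start
        if df2 <= 0 or rss_f <= 0:
            pvals[m] = 0.0
        else:
            f = ((rss_r - rss_f) / df1) / (rss_f / df2)
            pvals[m] = float(stats.f.sf(f, df1, df2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss_f / tss if tss > 0 else 0.0
    return coef, spans, pvals, r2


def backward_eliminate(
    trait_values: pd.Series,
    candidate_markers: list[str],
    matrix: GenotypeMatrix,
    trait: str = "trait",
    alpha: float = 0.05,
) -> MarkerLinearModel:
    """Multiple regression of a parameter on marker terms with backward
    elimination: starting from all candidates, the whole marker term with
    the largest partial-F p-value above ``alpha`` is dropped and the model
    refit, until every remaining term is significant.

    The reference allele of each term is its most frequent class (ties:
    lexicographically first).  Requires a complete (imputed) matrix on the
    genotypes carrying trait values.
    """
    gids = [g for g in matrix.genotype_ids if g in trait_values.index]
    gids = [g for g in gids if np.isfinite(trait_values[g])]
    calls = matrix.calls.loc[gids]
    y = trait_values.loc[gids].to_numpy(float)
    n = len(y)

    def design_of(m: str):
        col = calls[m].astype(str)
        if col.isin(["nan"]).any():
            raise ValueError(f"marker {m!r} has missing calls; impute first")
        counts = col.value_counts()
        ref = sorted(counts.index[counts == counts.max()])[0]
        others = sorted(c for c in counts.index if c != ref)
        if not others:
            return None
        D = np.column_stack([(col == c).to_numpy(float) for c in others])
        return D, others, ref

    designs = {}
    for m in candidate_markers:
        d = design_of(m)
        if d is not None:
            designs[m] = d
    n_coef = 1 + sum(d[0].shape[1] for d in designs.values())
    if n_coef >= n:
        raise ValueError(
            f"rank deficiency: {n_coef} coefficients for {n} genotypes; "
            "reduce the candidate set first"
        )

    coef, spans, pvals, r2 = (np.array([np.mean(y) if n else 0.0]), {}, {}, 0.0)
    while designs:
        coef, spans, pvals, r2 = _fit_marker_ols(y, designs)
        worst = max(pvals, key=lambda m: pvals[m])
        if pvals[worst] <= alpha:
            break
        del designs[worst]
    if not designs:
        return MarkerLinearModel(trait, float(np.mean(y)) if n else 0.0, [], 0.0)

    terms = []
    for m, (D, others, ref) in designs.items():
        effects = {
            allele: float(coef[spans[m].start + j]) for j, allele in enumerate(others)
        }
        terms.append(
            {
                "marker": m,
                "reference": ref,
                "effects": effects,
                "chromosome": str(matrix.meta.at[m, "chromosome"]),
            }
        )
    return MarkerLinearModel(trait, float(coef[0]), terms, float(r2))


def major_gene_model(
    trait_values: pd.Series,
    matrix: GenotypeMatrix,
    gene_marker_list: list[str],
    trait: str = "trait",
    alpha: float = 0.05,
) -> MarkerLinearModel:
    """Backward elimination restricted to a list of known major-gene markers
    (quantifies how much the minor QTLs add on top of the major genes)."""
    return backward_eliminate(trait_values, list(gene_marker_list), matrix, trait, alpha)


def load_bundled_model(trait: str) -> MarkerLinearModel:
    """The packaged reference marker model for ``"v_sat"`` or ``"p_base"``.

    Intercepts are 53.9 days (``v_sat``) and 4.85 hours (``p_base``);
    effects are additive deviations from the bracketed reference allele of
    each marker.
    """
    name = {"v_sat": "vsat_marker_model.json", "p_base": "pbase_marker_model.json"}
    if trait not in name:
        raise KeyError(f"no bundled model for trait {trait!r}")
    ref = resources.files("headcast.data").joinpath(name[trait])
    with ref.open() as fh:
        return MarkerLinearModel.from_json(fh)
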