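"""PCA of normalized exometabolome profiles across growth conditions.

Conditions are observations (rows) and metabolites variables (columns).
Columns are mean-centered but not variance-scaled — normalized values
already share a common [0, 1] scale.  The decomposition is by singular
values (scikit-learn's full-SVD solver) with a deterministic sign
convention: in each component the loading of largest magnitude is made
positive, so output is reproducible across runs and implementations.
Extreme loadings on a component identify the metabolites driving a
condition's separation.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datatypes import NormalizedExometabolome
from .errors import ValidationError


@dataclass(frozen=True)
class PcaResult:
    """Scores (condition x component), loadings (metabolite x component)
    and per-component explained variance (absolute and fractional)."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca(norm: NormalizedExometabolome, n_components: int | None = None,
        exclude_conditions: set[str] | None = None) -> PcaResult:
    """PCA of condition profiles (replicate-averaged normalized values).

    Parameters
    ----------
    n_components : number of components to keep (default: all).
    exclude_conditions : conditions dropped before the decomposition,
        e.g. no-growth cultures that have no exometabolome.
    """
    x = norm.values.T  # condition x metabolite
    if exclude_conditions:
        x = x.loc[[c for c in x.index if c not in exclude_conditions]]
    n_cond, n_met = x.shape
    if n_cond < 2 or n_met < 2:
        raise ValidationError("PCA needs >= 2 conditions and >= 2 metabolites")
    max_comp = min(n_cond, n_met)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ValidationError(
            f"n_components must be in [1, {max_comp}], got {n_components}")

    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x.to_numpy(dtype=float))
    loadings = model.components_.T  # metabolite x component, orthonormal

    # sign convention: largest-|loading| entry positive in every component
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    comps = [f"PC{j + 1}" for j in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=x.index, columns=comps),
        loadings=pd.DataFrame(loadings, index=x.columns, columns=comps),
        explained_variance=model.explained_variance_.copy(),
        explained_variance_fraction=model.explained_variance_ratio_.copy(),
    )


def top_loadings(res: PcaResult, component: str | int,
                 k: int = 5) -> tuple[pd.Series, pd.Series]:
    """The k most positive and k most negative loadings on a component.

    Both lists are ordered by loading magnitude (descending) with ties
    broken by metabolite id; only strictly positive (resp. negative)
    loadings qualify, so either list may be shorter than k (a warning is
    issued when it is truncated).
    """
    if isinstance(component, int):
        component = f"PC{component}"
    if component not in res.loadings.columns:
        raise ValidationError(f"component {component!r} not in result")
    if k < 0:
        raise ValidationError("k must be >= 0")
    col = res.loadings[component]

    def _top(series):
        df = pd.DataFrame({"loading": series, "met": series.index})
        df["mag"] = df["loading"].abs()
        df = df.sort_values(["mag", "met"], ascending=[False, True],
                            kind="mergesort")
        return df["loading"].head(k)

    pos = _top(col[col > 0])
    neg = _top(col[col < 0])
    if k > 0 and (len(pos) < k or len(neg) < k):
        warnings.warn(
            f"fewer than k={k} strictly positive/negative loadings on "
            f"{component}; lists truncated", stacklevel=2)
    return pos, neg
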