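"""Two-parameter description of ligand-dependent receptor states.

Chemical shifts measured across ligand complexes, together with ligand
descriptors (affinity pK_D, G-protein efficacy, head-group substituent
volume V_om), form a small ligands x observables matrix.  When the fast
conformational equilibrium of the receptor is governed by a low-dimensional
reaction coordinate, that matrix is approximately rank-2: a PCA retains
two components, and any well-conditioned pair of observables (e.g. the
1H/15N shifts of a single reporter residue) determines the two scores and
hence predicts every other observable.

Columns carry incommensurable units (ppm, %, Angstrom^3, pK units), so
columns are z-scored before the SVD by default; a center-only mode is
provided for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gpcrdyn")

#: condition-number threshold above which a predictor pair is rejected
PAIR_CONDITION_LIMIT = 1e6


@dataclass
class ObservationMatrix:
    """Complete ligands x observables table with optional class labels."""

    data: pd.DataFrame
    labels: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            cells = [(self.data.index[int(i)], self.data.columns[int(j)])
                     for i, j in np.argwhere(self.data.isna().values)]
            raise ValueError(f"missing cells (ligand, variable): {cells}")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.data.index)

    @property
    def n_entries(self) -> int:
        return int(self.data.size)


@dataclass
class PcaModel:
    """Column statistics, orthonormal loadings, scores and variance shares."""

    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray            # (n_vars, n_components)
    scores: np.ndarray              # (n_rows, n_components)
    explained_variance_ratio: np.ndarray
    columns: pd.Index
    index: pd.Index
    standardize: bool
    n_components: int


def assemble_matrix(shift_table: pd.DataFrame, ligand_table: pd.DataFrame
                    ) -> ObservationMatrix:
    """Build the ligands x observables matrix from long-format inputs.

    shift_table columns: ligand, residue, nucleus, ppm (one row per shift).
    ligand_table columns: ligand, pKD, efficacy_pct, vom_A3 and optionally
    pharm_class.  Shift columns are named '<residue>_<nucleus>'.  Every
    ligand must have every variable; missing cells are enumerated in the
    error.
    """
    required = {"ligand", "residue", "nucleus", "ppm"}
    if not required.issubset(shift_table.columns):
        raise ValueError(f"shift table needs columns {sorted(required)}")
    wide = shift_table.assign(
        variable=shift_table["residue"].astype(str) + "_"
        + shift_table["nucleus"].astype(str)
    ).pivot_table(index="ligand", columns="variable", values="ppm",
                  aggfunc="first")
    lig = ligand_table.set_index("ligand")
    labels = lig.pop("pharm_class") if "pharm_class" in lig.columns else None
    full = wide.join(lig, how="outer")
    matrix = ObservationMatrix(data=full, labels=labels)
    logger.info("assembled observation matrix: %d ligands x %d variables "
                "= %d entries", *full.shape, matrix.n_entries)
    return matrix


def fit_pca(m: ObservationMatrix | pd.DataFrame, standardize: bool = True
            ) -> PcaModel:
    """Column-centered (optionally z-scored) SVD of the observation matrix.

    With n rows, at most n-1 components carry variance; only those are
    retained.  Each loading column's largest-magnitude element is made
    positive so that output is reproducible across SVD implementations.
    """
    df = m.data if isinstance(m, ObservationMatrix) else m
    x = df.to_numpy(dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    mean = x.mean(axis=0)
    if standardize:
        scale = x.std(axis=0, ddof=1)
        zero = np.where(scale == 0)[0]
        if zero.size:
            raise ValueError(
                "zero-variance columns cannot be standardized: "
                f"{list(df.columns[zero])}")
    else:
        scale = np.ones(p)
    z = (x - mean) / scale
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    k = min(n - 1, p)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic sign: largest |loading| entry positive per component
    for j in range(k):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    var = s ** 2
    ratio = var / var.sum() if var.sum() > 0 else var
    return PcaModel(mean=mean, scale=scale, loadings=vt.T,
                    scores=u * s, explained_variance_ratio=ratio,
                    columns=df.columns, index=df.index,
                    standardize=standardize, n_components=k)


def reconstruct(model: PcaModel, n_components: int | None = None
                ) -> pd.DataFrame:
    """Low-rank reconstruction of the training matrix in original units."""
    k = model.n_components if n_components is None else n_components
    z = model.scores[:, :k] @ model.loadings[:, :k].T
    return pd.DataFrame(z * model.scale + model.mean,
                        index=model.index, columns=model.columns)


def predict_from_pair(model: PcaModel, var_i: str, var_j: str,
                      values: tuple, n_components: int = 2,
                      cond_limit: float = PAIR_CONDITION_LIMIT) -> tuple:
    """Predict all observables from one pair of measured observables.

    The two standardized measurements fix the n_components=2 scores through
    the 2x2 loading submatrix of (var_i, var_j); reconstructing all columns
    from those scores and un-standardizing with the training statistics
    yields the predictions.  Returns (predictions Series, condition number).
    A near-singular pair (condition number above cond_limit) is rejected
    with advice to pick a different pair.  Values outside the training
    range are extrapolations and produce a log warning, not an error.
    """
    cols = list(model.columns)
    try:
        ii, jj = cols.index(var_i), cols.index(var_j)
    except ValueError as err:
        raise KeyError(f"unknown variable in pair: {err}") from None
    if n_components > model.n_components:
        raise ValueError(f"model retains only {model.n_components} components")
    sub = model.loadings[[ii, jj], :n_components]
    cond = float(np.linalg.cond(sub))
    if not np.isfinite(cond) or cond > cond_limit:
        raise ValueError(
            f"pair ({var_i}, {var_j}) is near-singular (condition number "
            f"{cond:.3g}); choose a pair with independent loadings")
    z_pair = (np.asarray(values, dtype=float)
              - model.mean[[ii, jj]]) / model.scale[[ii, jj]]
    train = model.scores[:, :n_components]
    scores = np.linalg.solve(sub, z_pair)
    if np.any(scores < train.min(axis=0) - 1e-9) or \
            np.any(scores > train.max(axis=0) + 1e-9):
        logger.warning("predict_from_pair: scores %s outside the training "
                       "range; prediction is an extrapolation", scores)
    z_all = model.loadings[:, :n_components] @ scores
    pred = pd.Series(z_all * model.scale + model.mean, index=model.columns)
    return pred, cond


def scores_clusters(model: PcaModel, labels: pd.Series | None = None
                    ) -> pd.DataFrame:
    """PC1/PC2 coordinates per row with pass-through pharmacology labels.

    Cluster membership is left to visual inspection; no algorithmic
    grouping is claimed.
    """
    k = min(2, model.n_components)
    out = pd.DataFrame(model.scores[:, :k], index=model.index,
                       columns=["PC1", "PC2"][:k])
    if k < 2:
        out["PC2"] = 0.0
    if labels is not None:
        out["label"] = labels.reindex(model.index)
    return out
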