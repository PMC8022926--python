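"""Genomic prediction: single-kernel ridge-regression BLUP with REML.

The model is ``y = 1 b + Z u + e`` with marker effects
``u ~ iid N(0, var_u)`` and residuals ``e ~ iid N(0, var_e)``; ``Z`` is the
column-centered marker dosage matrix.  The variance ratio
``lambda = var_e / var_u`` is found by maximizing the restricted likelihood
on the spectrum of ``Z Z'`` (one-dimensional search in ``log lambda``,
tolerance 1e-8), after which the marker effects solve the mixed-model
equations at the optimum.

External predictors can be swapped in through :func:`export_training` /
:func:`import_ebv`: genotypes and phenotypes go out as CSV (and VCF),
predictions come back as an id-keyed EBV table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .population import Population

__all__ = [
    "GPModel",
    "make_marker_set",
    "fit_rrblup",
    "set_ebv",
    "export_training",
    "import_ebv",
]


@dataclass
class GPModel:
    """A fitted RR-BLUP model: marker addresses, intercept, effects,
    variance estimates, and the training-set column centering."""

    marker_chr: np.ndarray
    marker_idx: np.ndarray
    b: float
    u: np.ndarray
    var_u: float
    var_e: float
    centers: np.ndarray
    n_train: int

    @property
    def n_markers(self) -> int:
        return len(self.u)

    @property
    def h2(self) -> float:
        """Model-scale heritability: genetic variance captured by the
        markers (var_u * mean diagonal of ZZ') over total."""
        var_g = self.var_u * self._mean_diag
        return var_g / (var_g + self.var_e)

    _mean_diag: float = 0.0


def make_marker_set(haplo, n_markers: int, rng: np.random.Generator,
                    exclude_chr: Optional[np.ndarray] = None,
                    exclude_idx: Optional[np.ndarray] = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """A random "SNP chip": ``n_markers`` loci sampled uniformly across the
    genome, optionally excluding given (QTL) addresses."""
    pairs = [(c, i) for c in range(haplo.n_chr) for i in range(haplo.n_loci[c])]
    if exclude_chr is not None:
        banned = set(zip(map(int, exclude_chr), map(int, exclude_idx)))
        pairs = [p for p in pairs if p not in banned]
    if n_markers > len(pairs):
        raise ValueError("not enough loci for the requested marker count")
    pick = rng.choice(len(pairs), size=n_markers, replace=False)
    pick.sort()
    chosen = [pairs[k] for k in pick]
    return (np.array([c for c, _ in chosen], dtype=np.int64),
            np.array([i for _, i in chosen], dtype=np.int64))


def _reml_lambda(phi: np.ndarray, eta: np.ndarray, n: int) -> float:
    """Maximize the restricted likelihood over delta = var_e/var_u on the
    spectrum (phi, eta) of the intercept-projected ZZ'."""

    def neg_restricted_ll(log_d: float) -> float:
        d = np.exp(log_d)
        denom = phi + d
        s = np.sum(eta ** 2 / denom)
        return (n - 1) * np.log(s) + np.sum(np.log(denom))

    res = minimize_scalar(neg_restricted_ll, bounds=(-18.0, 18.0),
                          method="bounded",
                          options={"xatol": 1e-10})
    return float(np.exp(res.x))


def fit_rrblup(train_pop: Population, marker_chr: np.ndarray,
               marker_idx: np.ndarray, trait: int = 0,
               fixed_lambda: Optional[float] = None) -> GPModel:
    """Fit RR-BLUP on a phenotyped training population.

    ``fixed_lambda`` skips REML and solves the mixed-model equations at the
    given variance ratio (mainly for validation against direct solvers).
    """
    if train_pop.pheno is None:
        raise ValueError("training population has no phenotypes")
    if train_pop.n_ind < 2:
        raise ValueError("need at least two training individuals")
    marker_chr = np.asarray(marker_chr, dtype=np.int64)
    marker_idx = np.asarray(marker_idx, dtype=np.int64)
    if len(marker_chr) == 0:
        raise ValueError("marker set is empty")
    y = train_pop.pheno[:, trait].astype(float)
    if fixed_lambda is None and np.var(y) == 0:
        raise ValueError("phenotypes have zero variance; the variance ratio "
                         "cannot be estimated")
    n = len(y)
    X = train_pop.haplo.dosages_at(marker_chr, marker_idx).astype(float)
    centers = X.mean(axis=0)
    Z = X - centers
    K = Z @ Z.T
    mean_diag = float(np.trace(K)) / n

    if fixed_lambda is None:
        # project out the intercept and eigendecompose
        Kc = K - K.mean(axis=0) - K.mean(axis=1)[:, None] + K.mean()
        yc = y - y.mean()
        phi, U = np.linalg.eigh(Kc)
        # drop the null direction along the 1 vector (its eta is 0); with a
        # degenerate null space pick the eigenvector most aligned with 1
        align = np.abs(U.T @ np.full(n, 1.0 / np.sqrt(n)))
        drop = int(np.argmax(align))
        keep = np.ones(n, dtype=bool)
        keep[drop] = False
        phi = np.maximum(phi[keep], 0.0)
        eta = (U.T @ yc)[keep]
        lam = _reml_lambda(phi, eta, n)
        var_u = float(np.sum(eta ** 2 / (phi + lam)) / (n - 1))
        var_e = lam * var_u
    else:
        lam = float(fixed_lambda)
        var_u = float("nan")
        var_e = float("nan")

    # GLS intercept and marker effects at the optimum
    V = K + lam * np.eye(n)
    Vinv_1 = np.linalg.solve(V, np.ones(n))
    Vinv_y = np.linalg.solve(V, y)
    b = float(np.sum(Vinv_y) / np.sum(Vinv_1))
    u = Z.T @ np.linalg.solve(V, y - b)

    model = GPModel(marker_chr=marker_chr, marker_idx=marker_idx, b=b,
                    u=u, var_u=var_u, var_e=var_e, centers=centers,
                    n_train=n)
    model._mean_diag = mean_diag
    return model


def set_ebv(pop: Population, model: GPModel, trait: int = 0) -> Population:
    """Write estimated breeding values ``b + Z_new u`` into a population,
    using the training-set centering."""
    max_idx = np.asarray(pop.haplo.n_loci)[model.marker_chr]
    if np.any(model.marker_idx >= max_idx):
        raise ValueError("model marker addresses are missing from this "
                         "population's genome")
    X = pop.haplo.dosages_at(model.marker_chr, model.marker_idx).astype(float)
    pred = model.b + (X - model.centers) @ model.u
    out = pop.subset(np.arange(pop.n_ind))
    n_t = pop.gv.shape[1]
    ebv = pop.ebv.copy() if pop.ebv is not None else np.full((pop.n_ind, n_t),
                                                             np.nan)
    ebv[:, trait] = pred
    out.ebv = ebv
    return out


def export_training(pop: Population, pheno_path: str, geno_path: str,
                    marker_chr: Optional[np.ndarray] = None,
                    marker_idx: Optional[np.ndarray] = None,
                    vcf_path: Optional[str] = None) -> None:
    """Write training data for an external predictor: phenotypes as CSV
    (id, one column per trait) and marker dosages as CSV (id, one column
    per marker); optionally the full phased genotypes as VCF."""
    if pop.pheno is None:
        raise ValueError("population has no phenotypes to export")
    ph = pd.DataFrame({"id": pop.ids})
    for t in range(pop.pheno.shape[1]):
        ph[f"pheno{t + 1}"] = pop.pheno[:, t]
    ph.to_csv(pheno_path, index=False)
    if marker_chr is None:
        X = pop.haplo.dosages()
        cols = [f"m{k + 1}" for k in range(X.shape[1])]
    else:
        X = pop.haplo.dosages_at(marker_chr, marker_idx)
        cols = [f"c{c + 1}_l{i + 1}" for c, i in zip(marker_chr, marker_idx)]
    geno = pd.DataFrame(X, columns=cols)
    geno.insert(0, "id", pop.ids)
    geno.to_csv(geno_path, index=False)
    if vcf_path is not None:
        from .founders import export_haplotypes

        export_haplotypes(pop.haplo, pop.sp.gmap, vcf_path,
                          sample_ids=[str(i) for i in pop.ids])


def import_ebv(pop: Population, table: str | pd.DataFrame,
               trait_columns: Optional[Sequence[str]] = None) -> Population:
    """Read externally computed EBVs back into a population.

    ``table`` is a CSV path or DataFrame with an ``id`` column and one EBV
    column per trait.  Ids must all exist in the population; malformed rows
    are reported with their line number.
    """
    if isinstance(table, (str,)):
        df = pd.read_csv(table)
    else:
        df = table.copy()
    if "id" not in df.columns:
        raise ValueError("EBV table needs an 'id' column")
    if trait_columns is None:
        trait_columns = [c for c in df.columns if c != "id"]
    n_t = pop.gv.shape[1]
    if len(trait_columns) != n_t:
        raise ValueError(
            f"expected {n_t} trait column(s), found {len(trait_columns)}"
        )
    for col in trait_columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"malformed EBV value in column {col!r} at line "
                f"{int(bad[0]) + 2}"
            )
    idx = pop.index_of_ids(df["id"].tolist())
    out = pop.subset(np.arange(pop.n_ind))
    ebv = np.full((pop.n_ind, n_t), np.nan)
    for t, col in enumerate(trait_columns):
        ebv[idx, t] = pd.to_numeric(df[col]).to_numpy()
    out.ebv = ebv
    return out
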