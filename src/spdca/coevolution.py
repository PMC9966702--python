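"""Potts-model inference on paired alignments (plmDCA) and coupling scores.

Direct coupling analysis fits a global pairwise (Potts) model

    P(x) ∝ exp( Σ_i h_i(x_i) + Σ_{i<j} J_ij(x_i, x_j) )

to an alignment so that direct residue-residue couplings are separated
from transitive correlations.  The fit here is pseudo-likelihood
maximization (plmDCA): the product of per-column conditional likelihoods
is maximized with L2 regularization, which is consistent, convex, and far
cheaper than the full likelihood.  Couplings are summarized per column
pair by the Frobenius norm of the zero-sum-gauge coupling block,
optionally with the average product correction (APC); the inter-protein
sub-block of that score matrix is the evolutionary score P_ij consumed by
the structure-prior convolution.

Sequences are reweighted by local density (weight 1/n of each cluster of
mutually similar rows) so that over-represented taxa do not dominate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse

from .alignment import AA_ALPHABET, PairedAlignment


class ConvergenceError(RuntimeError):
    """Pseudo-likelihood optimization failed to reach tolerance."""


def synthetic_alphabet(q: int) -> str:
    """A gap-free residue alphabet of size q (used by the MSA simulator)."""
    letters = AA_ALPHABET[:-1]
    if not 2 <= q <= len(letters):
        raise ValueError(f"alphabet size must be in [2, {len(letters)}]")
    return letters[:q]


def encode(rows: np.ndarray, alphabet: str = AA_ALPHABET) -> np.ndarray:
    """Map an (M, L) symbol matrix to integer state indices."""
    rows = np.asarray(rows, dtype="U1")
    lut = {c: i for i, c in enumerate(alphabet)}
    try:
        flat = np.array([lut[c] for c in rows.ravel()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"symbol {exc} not in alphabet {alphabet!r}") from exc
    return flat.reshape(rows.shape)


# ---------------------------------------------------------------------------
# Sequence reweighting


@dataclass
class SequenceWeights:
    """Per-row weights 1/(cluster size) at identity threshold ``theta``."""

    weights: np.ndarray
    theta: float

    @property
    def m_eff(self) -> float:
        return float(self.weights.sum())


def sequence_weights(
    pa: PairedAlignment, theta: float = 0.8, chunk: int = 256
) -> SequenceWeights:
    """Down-weight redundant rows: weight_r = 1 / #{rows with identity ≥ theta to r}.

    Identity is the plain fraction of equal symbols over all concatenated
    columns (gaps compare as a state, the standard DCA convention).
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must be in (0, 1]")
    X = np.asarray(pa.rows, dtype="U1")
    M, L = X.shape
    counts = np.zeros(M, dtype=np.int64)
    # chunked pairwise comparison keeps memory at O(chunk * M * L) bytes
    codes = X.view(np.uint32)  # compare as code points, cheaper than U1
    for lo in range(0, M, chunk):
        hi = min(lo + chunk, M)
        sim = (codes[lo:hi, None, :] == codes[None, :, :]).mean(axis=2)
        counts[lo:hi] = (sim >= theta).sum(axis=1)
    return SequenceWeights(weights=1.0 / counts, theta=theta)


# ---------------------------------------------------------------------------
# Potts model


@dataclass
class PottsModel:
    """Fields and pairwise couplings over a residue alphabet.

    ``couplings[i, j]`` is the q×q block J_ij; after fitting it is
    symmetric (J_ij(s,t) = J_ji(t,s)), zero on the diagonal blocks and in
    the zero-sum gauge, with fields compensated so the joint distribution
    is unchanged by the gauge choice.
    """

    q: int
    fields: np.ndarray            # (L, q)
    couplings: np.ndarray         # (L, L, q, q)
    alphabet: str = ""
    reg_fields: float = 0.0
    reg_couplings: float = 0.0
    len_a: int | None = None      # block boundary when fitted on a PairedAlignment
    meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.fields.shape[0]

    @property
    def gap_index(self) -> int | None:
        i = self.alphabet.find("-")
        return None if i < 0 else i


def zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Shift couplings to the zero-sum gauge, compensating the fields.

    For each pair, J'_ij = J_ij − rowmean − colmean + mean and
    h'_i(s) = h_i(s) + Σ_j (mean_t J_ij(s,t) − mean_st J_ij); the joint
    Potts measure is unchanged.
    """
    J = model.couplings
    row = J.mean(axis=3, keepdims=True)       # mean over t
    col = J.mean(axis=2, keepdims=True)       # mean over s
    tot = J.mean(axis=(2, 3), keepdims=True)
    J_fixed = J - row - col + tot
    h_fixed = model.fields + (row - tot)[:, :, :, 0].sum(axis=1)
    return PottsModel(
        q=model.q,
        fields=h_fixed,
        couplings=J_fixed,
        alphabet=model.alphabet,
        reg_fields=model.reg_fields,
        reg_couplings=model.reg_couplings,
        len_a=model.len_a,
        meta=dict(model.meta),
    )


def _one_hot(X: np.ndarray, q: int) -> scipy.sparse.csr_matrix:
    M, L = X.shape
    cols = (np.arange(L)[None, :] * q + X).ravel()
    rows = np.repeat(np.arange(M), L)
    data = np.ones(M * L)
    return scipy.sparse.csr_matrix((data, (rows, cols)), shape=(M, L * q))


def _plm_objective(x, Z, ZT, X, w, L, q, lam_h, lam_J, B, diag_mask):
    """Normalized weighted negative log pseudo-likelihood and gradient.

    Parameters are h (L, q) and the asymmetric coupling tensor packed as
    T[(j,t), (i,s)] = J_i←j(s,t); diagonal blocks are frozen at zero.
    """
    M = X.shape[0]
    h = x[: L * q].reshape(L, q)
    T = x[L * q :].reshape(L * q, L * q)

    A = Z @ T                              # (M, Lq): Σ_j J_i(s, x_j)
    phi = A.reshape(M, L, q) + h[None, :, :]
    mx = phi.max(axis=2, keepdims=True)
    ex = np.exp(phi - mx)
    sm = ex.sum(axis=2, keepdims=True)
    lse = (mx + np.log(sm))[:, :, 0]
    obs = np.take_along_axis(phi, X[:, :, None], axis=2)[:, :, 0]
    nll = float((w * (lse - obs).sum(axis=1)).sum() / B)

    P = ex / sm                            # softmax
    D = P * (w / B)[:, None, None]
    # each (m, i) index pair occurs exactly once → plain fancy indexing is safe
    D[np.arange(M)[:, None], np.arange(L)[None, :], X] -= (w / B)[:, None]
    grad_h = D.sum(axis=0)
    Dm = D.reshape(M, L * q)
    grad_T = ZT @ Dm                       # (Lq, Lq)
    grad_T[diag_mask] = 0.0

    f = nll + (lam_h * (h ** 2).sum() + lam_J * (T ** 2).sum()) / B
    grad_h = grad_h + 2.0 * lam_h / B * h
    grad_T = grad_T + 2.0 * lam_J / B * T
    return f, np.concatenate([grad_h.ravel(), grad_T.ravel()])


def fit_plm(
    pa: PairedAlignment,
    w: SequenceWeights | None = None,
    reg_fields: float = 0.01,
    reg_couplings: float | None = None,
    alphabet: str = AA_ALPHABET,
    gtol: float = 1e-5,
    maxiter: int = 2000,
) -> PottsModel:
    """Fit a Potts model by weighted, L2-regularized pseudo-likelihood.

    All per-column conditional (multinomial logistic) problems are solved
    jointly with L-BFGS; the two asymmetric estimates of each J_ij are then
    averaged and the result gauge-fixed to zero-sum.  ``reg_couplings``
    defaults to 0.01·(L−1).  Deterministic given inputs and tolerance.

    Raises :class:`ConvergenceError` if the optimizer stops with a
    projected gradient above ``gtol`` (diagnostics attached).
    """
    if pa.n_rows == 0:
        raise ValueError("cannot fit a Potts model on an empty alignment")
    X = encode(pa.rows, alphabet)
    M, L = X.shape
    q = len(alphabet)
    if w is None:
        w = sequence_weights(pa)
    weights = np.asarray(w.weights, dtype=float)
    if weights.shape != (M,):
        raise ValueError("weights do not match alignment rows")
    B = float(weights.sum())
    if reg_couplings is None:
        reg_couplings = 0.01 * (L - 1)
    if reg_fields <= 0 or reg_couplings <= 0:
        raise ValueError("regularization strengths must be positive")

    Z = _one_hot(X, q)
    ZT = scipy.sparse.csr_matrix(Z.T)
    diag_mask = np.zeros((L * q, L * q), dtype=bool)
    for i in range(L):
        diag_mask[i * q : (i + 1) * q, i * q : (i + 1) * q] = True

    x0 = np.zeros(L * q + (L * q) ** 2)
    res = scipy.optimize.minimize(
        _plm_objective,
        x0,
        args=(Z, ZT, X, weights, L, q, reg_fields, reg_couplings, B, diag_mask),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12, "maxfun": 4 * maxiter},
    )
    grad_inf = float(np.abs(res.jac).max())
    if grad_inf > 10 * gtol:
        raise ConvergenceError(
            f"plmDCA optimizer stopped ({res.message}) with projected gradient "
            f"{grad_inf:.2e} > {gtol:.0e}; nit={res.nit}, nfev={res.nfev}"
        )

    h = res.x[: L * q].reshape(L, q)
    T = res.x[L * q :].reshape(L * q, L * q)
    # T[(j,t),(i,s)] = J_i←j(s,t)  →  J_asym[i,j,s,t]
    J_asym = T.reshape(L, q, L, q).transpose(2, 0, 3, 1)
    J_sym = 0.5 * (J_asym + J_asym.transpose(1, 0, 3, 2))
    model = PottsModel(
        q=q,
        fields=h,
        couplings=J_sym,
        alphabet=alphabet,
        reg_fields=reg_fields,
        reg_couplings=reg_couplings,
        len_a=pa.len_a,
        meta={
            "method": "plm",
            "n_rows": M,
            "m_eff": B,
            "theta": w.theta,
            "n_iter": int(res.nit),
            "n_fev": int(res.nfev),
            "grad_inf": grad_inf,
            "converged": bool(grad_inf <= 10 * gtol),
        },
    )
    return zero_sum_gauge(model)


def fit_mean_field(
    pa: PairedAlignment,
    w: SequenceWeights | None = None,
    pseudocount: float = 0.5,
    alphabet: str = AA_ALPHABET,
) -> PottsModel:
    """Mean-field DCA: couplings from the inverse regularized covariance.

    An independent, closed-form cross-check for the pseudo-likelihood
    path — less accurate, but it must agree on strong couplings.
    """
    X = encode(pa.rows, alphabet)
    M, L = X.shape
    q = len(alphabet)
    if w is None:
        w = sequence_weights(pa)
    weights = np.asarray(w.weights, dtype=float)
    B = weights.sum()

    # weighted single and pair frequencies with uniform pseudocount
    oh = np.zeros((M, L, q))
    oh[np.arange(M)[:, None], np.arange(L)[None, :], X] = 1.0
    lam = pseudocount
    fi = (1 - lam) * np.einsum("m,mia->ia", weights, oh) / B + lam / q
    ohw = oh * weights[:, None, None]
    fij = (1 - lam) * np.einsum("mia,mjb->iajb", ohw, oh) / B + lam / q ** 2
    for i in range(L):
        # the i=j block is the single-site frequency on the diagonal
        fij[i, :, i, :] = (
            (1 - lam) * np.einsum("m,ma,mb->ab", weights, oh[:, i], oh[:, i]) / B
            + lam / q * np.eye(q)
        )

    # covariance over the first q-1 states; invert; J = -C^{-1}
    C = fij - np.einsum("ia,jb->iajb", fi, fi)
    k = q - 1
    Cm = C[:, :k, :, :k].reshape(L * k, L * k)
    Jm = -np.linalg.inv(Cm)
    J = np.zeros((L, L, q, q))
    J[:, :, :k, :k] = Jm.reshape(L, k, L, k).transpose(0, 2, 1, 3)
    for i in range(L):
        J[i, i] = 0.0
    J = 0.5 * (J + J.transpose(1, 0, 3, 2))
    model = PottsModel(
        q=q,
        fields=np.log(fi + 1e-12),
        couplings=J,
        alphabet=alphabet,
        len_a=pa.len_a,
        meta={"method": "mean_field", "n_rows": M, "m_eff": float(B),
              "pseudocount": pseudocount, "theta": w.theta},
    )
    return zero_sum_gauge(model)


def pseudolikelihood(
    model: PottsModel, pa: PairedAlignment, weights: np.ndarray | None = None
) -> float:
    """Weighted log pseudo-likelihood Σ_m w_m Σ_i log P(x_i | x_others)."""
    X = encode(pa.rows, model.alphabet or AA_ALPHABET)
    M, L = X.shape
    q = model.q
    if weights is None:
        weights = np.ones(M)
    # phi[m, i, s] = h_i(s) + Σ_{j≠i} J_ij(s, x_j); plain loops, used on
    # small inputs (exhaustive oracle checks) where clarity wins
    phi = np.empty((M, L, q))
    for m in range(M):
        for i in range(L):
            others = np.arange(L) != i
            phi[m, i] = model.fields[i] + model.couplings[
                i, others, :, X[m, others]
            ].sum(axis=0)
    mx = phi.max(axis=2, keepdims=True)
    lse = (mx[:, :, 0] + np.log(np.exp(phi - mx).sum(axis=2)))
    obs = np.take_along_axis(phi, X[:, :, None], axis=2)[:, :, 0]
    return float((weights * (obs - lse).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# Coupling scores


@dataclass
class CouplingMatrix:
    """Symmetric per-pair coupling scores S_ij with optional APC."""

    scores: np.ndarray
    apc_applied: bool
    len_a: int | None = None
    raw_scores: np.ndarray | None = None

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def inter_block(self) -> np.ndarray:
        if self.len_a is None:
            raise ValueError("no block boundary recorded on this CouplingMatrix")
        return inter_protein_block(self, self.len_a, self.length - self.len_a)


def apc_correct(S: np.ndarray, clip: bool = True) -> np.ndarray:
    """Average product correction, computed excluding the diagonal.

    S_ij ← S_ij − S̄_i· S̄_·j / S̄, the standard background correction for
    entropic/phylogenetic bias.  Negative corrected values are clipped to
    zero by default (scores feed a nonnegativity-assuming convolution).
    """
    S = np.asarray(S, dtype=float)
    L = S.shape[0]
    if L < 2:
        return np.zeros_like(S)
    off = ~np.eye(L, dtype=bool)
    row_mean = (S.sum(axis=1) - np.diag(S)) / (L - 1)
    total_mean = S[off].mean()
    if total_mean == 0:
        corrected = S - 0.0
    else:
        corrected = S - np.outer(row_mean, row_mean) / total_mean
    np.fill_diagonal(corrected, 0.0)
    if clip:
        corrected = np.clip(corrected, 0.0, None)
    return corrected


def coupling_scores(model: PottsModel, apply_apc: bool = True) -> CouplingMatrix:
    """Frobenius-norm coupling scores, optionally APC-corrected.

    The norm is taken over non-gap states of the zero-sum-gauge coupling
    blocks, so alignment gaps cannot drive interface scores.
    """
    fixed = zero_sum_gauge(model)
    J = fixed.couplings
    gi = model.gap_index
    if gi is not None:
        keep = np.arange(model.q) != gi
        J = J[:, :, keep][:, :, :, keep]
    S = np.sqrt((J ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(S, 0.0)
    scores = apc_correct(S) if apply_apc else S
    return CouplingMatrix(
        scores=scores, apc_applied=apply_apc, len_a=model.len_a, raw_scores=S
    )


def inter_protein_block(
    cm: CouplingMatrix, len_a: int, len_b: int
) -> np.ndarray:
    """The len_a × len_b inter-protein sub-matrix P_ij of the score matrix.

    Rows index protein-A columns, columns protein-B columns; intra-protein
    scores are discarded — only cross-protein coevolution predicts the
    interface.
    """
    if len_a + len_b != cm.length:
        raise ValueError(
            f"len_a + len_b = {len_a + len_b} does not match matrix size {cm.length}"
        )
    return cm.scores[:len_a, len_a:].copy()


def top_pairs(block: np.ndarray) -> list[tuple[int, int]]:
    """All (i, j) inter-block index pairs ranked by descending score."""
    order = np.argsort(block, axis=None)[::-1]
    return [tuple(divmod(int(k), block.shape[1])) for k in order]


def write_scores_tsv(
    cm: CouplingMatrix, pa: PairedAlignment, path: str | Path
) -> None:
    """Scores as TSV with 1-based indices and consensus residue letters."""
    L = cm.length
    # consensus (modal) symbol per column, for readability only
    def consensus(col: np.ndarray) -> str:
        vals, counts = np.unique(col, return_counts=True)
        return str(vals[counts.argmax()])

    cons = [consensus(pa.rows[:, i]) for i in range(L)]
    i_idx, j_idx = np.triu_indices(L, k=1)
    raw = cm.raw_scores if cm.raw_scores is not None else cm.scores
    df = pd.DataFrame(
        {
            "i": i_idx + 1,
            "j": j_idx + 1,
            "residue_a": [cons[i] for i in i_idx],
            "residue_b": [cons[j] for j in j_idx],
            "raw_score": raw[i_idx, j_idx],
            "apc_score": cm.scores[i_idx, j_idx] if cm.apc_applied else np.nan,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
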