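"""MVAR fitting and partial directed coherence (PDC).

A multivariate autoregressive model of order p over N channels,

    x_t = A_1 x_{t-1} + ... + A_p x_{t-p} + e_t,

is fitted by ordinary least squares on the stacked lag regression, with the
order chosen by minimum BIC when unspecified.  From the coefficients two
frequency-domain objects follow on a grid f:

    Abar(f) = I - sum_k A_k exp(-i 2 pi f k / rate)
    H(f)    = Abar(f)^{-1}            (the transfer function)

Two PDC variants are exposed.  The default, ``H``, normalizes |H_ij(f)|^2
by its column sum over targets -- note that an H-based quantity is
conventionally the DTF, but this normalization is what several applied
corticomuscular analyses report under the PDC name; ``Abar`` is the textbook
PDC built from Abar(f) with column normalization.  Both lie in [0, 1]; ``H``
columns sum to exactly 1.

For the corticomuscular analysis a 3-channel model (C3, C4, EMG) is fitted
per subject and condition on a continuous segment, PDC is averaged within
the beta / gamma1 / gamma2 bands, and condition contrasts are paired-tested
with BH-FDR over the (directed pair x band) family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import PairedSample, fdr_bh, paired_t


class MvarError(ValueError):
    pass


@dataclass
class MvarModel:
    """Fitted (or specified) MVAR coefficients.

    ``coefs`` has shape ``(p, N, N)``; ``coefs[k][i, j]`` multiplies channel j
    at lag k+1 in the prediction of channel i.
    """

    coefs: np.ndarray
    noise_cov: np.ndarray
    rate: float
    labels: list | None = None
    bic: float | None = None
    stable: bool | None = None

    def __post_init__(self) -> None:
        self.coefs = np.asarray(self.coefs, dtype=float)
        if self.coefs.ndim != 3 or self.coefs.shape[1] != self.coefs.shape[2]:
            raise MvarError(f"coefs must be (p, N, N), got {self.coefs.shape}")
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.stable is None:
            self.stable = bool(companion_spectral_radius(self.coefs) < 1.0)

    @property
    def order(self) -> int:
        return self.coefs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefs.shape[1]


def companion_spectral_radius(coefs: np.ndarray) -> float:
    """Spectral radius of the companion matrix; < 1 means a stable model."""
    coefs = np.asarray(coefs, dtype=float)
    p, n, _ = coefs.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(coefs), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _ols_fit(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray, float]:
    """OLS MVAR(p) fit; returns (coefs, residual covariance, log-likelihood BIC)."""
    n_ch, n_s = x.shape
    if n_s - p < n_ch * p + 1:
        raise MvarError(f"too few samples ({n_s}) for order {p} with {n_ch} channels")
    y = x[:, p:].T  # (T, N)
    design = np.hstack([x[:, p - k : n_s - k].T for k in range(1, p + 1)])  # (T, N*p)
    beta, residues, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise MvarError(f"rank-deficient lag regression at order {p}")
    resid = y - design @ beta
    t_eff = y.shape[0]
    sigma = resid.T @ resid / t_eff
    coefs = np.stack(
        [beta[k * n_ch : (k + 1) * n_ch].T for k in range(p)], axis=0
    )
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        logdet = np.log(np.linalg.det(sigma + 1e-12 * np.eye(n_ch)))
    bic = t_eff * logdet + np.log(t_eff) * (p * n_ch * n_ch)
    return coefs, sigma, float(bic)


def fit_mvar(
    data: np.ndarray,
    rate: float,
    order: int | None = None,
    max_order: int = 20,
    labels: list | None = None,
) -> MvarModel:
    """Fit an MVAR model to ``(N, n_samples)`` data by least squares.

    Data are demeaned internally.  When ``order`` is None the order minimizing
    BIC over 1..max_order is used.  An unstable fit is returned with
    ``stable=False`` (downstream code can decide to refuse it).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise MvarError("data must be (channels, samples)")
    x = x - x.mean(axis=1, keepdims=True)
    if order is not None:
        coefs, sigma, bic = _ols_fit(x, order)
    else:
        best = None
        for p in range(1, max_order + 1):
            try:
                cand = _ols_fit(x, p)
            except MvarError:
                break
            if best is None or cand[2] < best[2]:
                best = cand
        if best is None:
            raise MvarError("no MVAR order could be fitted")
        coefs, sigma, bic = best
    model = MvarModel(coefs=coefs, noise_cov=sigma, rate=rate, labels=labels, bic=bic)
    return model


@dataclass
class PdcSpectrum:
    """PDC_ij(f): influence of source channel j on target channel i."""

    freqs: np.ndarray
    values: np.ndarray  # (n_freqs, N, N), target i, source j
    variant: str
    labels: list | None = None

    def pair(self, target: int, source: int) -> np.ndarray:
        return self.values[:, target, source]


def transfer_function(model: MvarModel, freqs: np.ndarray) -> np.ndarray:
    """H(f) = [I - sum_k A_k exp(-i 2 pi f k / rate)]^{-1}, shape (F, N, N)."""
    if not model.stable:
        raise MvarError("transfer function of an unstable model is undefined")
    freqs = np.asarray(freqs, dtype=float)
    p, n, _ = model.coefs.shape
    k = np.arange(1, p + 1)
    # phase factors: (F, p)
    ph = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] / model.rate)
    abar = np.eye(n)[None, :, :] - np.einsum("fp,pij->fij", ph, model.coefs)
    try:
        return np.linalg.inv(abar)
    except np.linalg.LinAlgError as exc:
        raise MvarError(f"singular Abar(f) on the requested grid: {exc}") from exc


def spectral_abar(model: MvarModel, freqs: np.ndarray) -> np.ndarray:
    """Abar(f) = I - sum_k A_k exp(-i 2 pi f k / rate), shape (F, N, N)."""
    freqs = np.asarray(freqs, dtype=float)
    p, n, _ = model.coefs.shape
    k = np.arange(1, p + 1)
    ph = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] / model.rate)
    return np.eye(n)[None, :, :] - np.einsum("fp,pij->fij", ph, model.coefs)


def pdc(model: MvarModel, freqs: np.ndarray | None = None, variant: str = "H") -> PdcSpectrum:
    """Partial directed coherence spectrum on a frequency grid.

    ``H``: |H_ij|^2 / sum_k |H_kj|^2 (column-normalized transfer
    function; per-source columns sum to 1 at every frequency).
    ``Abar``: |Abar_ij|^2 / sum_k |Abar_kj|^2 (textbook PDC).
    """
    if freqs is None:
        freqs = np.arange(1.0, 100.5, 0.5)
    freqs = np.asarray(freqs, dtype=float)
    if variant == "H":
        mat = transfer_function(model, freqs)
    elif variant == "Abar":
        mat = spectral_abar(model, freqs)
    else:
        raise MvarError(f"unknown PDC variant {variant!r}")
    mag2 = np.abs(mat) ** 2
    colsum = mag2.sum(axis=1, keepdims=True)  # sum over targets per source column
    if np.any(colsum == 0):
        raise MvarError("zero denominator column in PDC normalization")
    return PdcSpectrum(freqs=freqs, values=mag2 / colsum, variant=variant,
                       labels=model.labels)


def band_pdc(spec: PdcSpectrum, band: tuple[float, float]) -> np.ndarray:
    """Arithmetic mean of PDC over the in-band frequency bins, shape (N, N)."""
    lo, hi = band
    m = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(m):
        raise MvarError(f"no frequency bins inside band {band}")
    return spec.values[m].mean(axis=0)


#: Directed pairs reported in the corticomuscular contrast (source -> target).
CONTRAST_PAIRS = (
    ("C3", "EMG"), ("C4", "EMG"), ("EMG", "C3"), ("EMG", "C4"),
    ("C3", "C4"), ("C4", "C3"),
)

CONTRAST_BANDS = {"beta": (13.0, 30.0), "gamma1": (30.0, 60.0), "gamma2": (60.0, 100.0)}


def pdc_contrast(
    band_pdc_a: pd.DataFrame,
    band_pdc_b: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Paired contrast of per-subject band PDC between two conditions.

    Inputs are long tables with columns ``subject, source, target, band,
    value`` covering every directed pair and band for the same subjects.
    Returns per (pair, band): t, p, BH-FDR significance over the whole
    family, and the direction of the mean change (a - b).
    """
    rows = []
    for (src, tgt) in {(s, t) for s, t in zip(band_pdc_a["source"], band_pdc_a["target"])}:
        for band in sorted(band_pdc_a["band"].unique()):
            sel_a = band_pdc_a[
                (band_pdc_a.source == src) & (band_pdc_a.target == tgt) & (band_pdc_a.band == band)
            ].sort_values("subject")
            sel_b = band_pdc_b[
                (band_pdc_b.source == src) & (band_pdc_b.target == tgt) & (band_pdc_b.band == band)
            ].sort_values("subject")
            if len(sel_a) == 0 or len(sel_a) != len(sel_b) or not (
                sel_a["subject"].values == sel_b["subject"].values
            ).all():
                raise MvarError(f"unmatched subjects for pair {src}->{tgt}, band {band}")
            t, p = paired_t(PairedSample(sel_a["value"].values, sel_b["value"].values))
            diff = float(sel_a["value"].values.mean() - sel_b["value"].values.mean())
            rows.append({
                "source": src, "target": tgt, "band": band,
                "t": t, "p": p, "mean_diff": diff,
                "direction": "increased" if diff > 0 else "decreased",
            })
    out = pd.DataFrame(rows)
    out["significant"] = fdr_bh(out["p"].values, q=q)
    return out.sort_values(["band", "source", "target"]).reset_index(drop=True)
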