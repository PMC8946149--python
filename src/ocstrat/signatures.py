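"""Mutational signature refitting and cohort-level signature selection.

Signature refitting estimates non-negative absolute contributions of
catalog signatures to an observed context count vector by minimising the
least-squares reconstruction error.  The optimiser is cyclic coordinate
descent where every coordinate update is a golden-section line search on
[0, sum(counts)]; because the objective is convex and coordinatewise
smooth, the optimum agrees with a non-negative least squares (NNLS)
solution, which serves as the independent oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0  # inverse golden ratio

_DATA = Path(__file__).parent / "data"


@dataclass
class SignatureCatalog:
    """Named signature profiles over a fixed context-key scheme."""

    names: list[str]
    context_keys: list[str]
    profiles: np.ndarray  # (n_signatures, n_contexts), rows sum to 1

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (len(self.names), len(self.context_keys)):
            raise ValueError("profile matrix shape does not match names/keys")
        if np.any(self.profiles < 0):
            raise ValueError("signature profiles must be non-negative")
        sums = self.profiles.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = [n for n, s in zip(self.names, sums) if abs(s - 1.0) > 1e-6]
            raise ValueError(f"profiles do not sum to 1: {bad}")

    def subset(self, names: list[str]) -> "SignatureCatalog":
        idx = [self.names.index(n) for n in names]
        return SignatureCatalog(list(names), self.context_keys, self.profiles[idx])

    def __len__(self) -> int:
        return len(self.names)


def read_catalog(path) -> SignatureCatalog:
    """Read a COSMIC-format catalog CSV (first column = context key)."""
    df = pd.read_csv(path)
    keys = df.iloc[:, 0].astype(str).tolist()
    names = list(df.columns[1:])
    profiles = df.iloc[:, 1:].to_numpy(dtype=float).T
    profiles = profiles / profiles.sum(axis=1, keepdims=True)
    return SignatureCatalog(names, keys, profiles)


def packaged_catalog(scheme: str) -> SignatureCatalog:
    """Load the packaged *synthetic* catalog for scheme in {sbs, dbs, id}.

    These are synthetic stand-ins in COSMIC CSV layout, sufficient for the
    simulator and the tests; real COSMIC downloads can be supplied to
    :func:`read_catalog` instead.
    """
    return read_catalog(_DATA / f"{scheme}_catalog_synthetic.csv")


@dataclass
class SignatureFit:
    names: list[str]
    contributions: np.ndarray  # absolute mutation counts per signature
    reconstruction_cosine: float
    residual_sse: float

    def relative(self) -> np.ndarray:
        total = self.contributions.sum()
        if total == 0:
            return np.zeros_like(self.contributions)
        return self.contributions / total

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.contributions))


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _golden_section_min(f, lo: float, hi: float, tol: float) -> float:
    """Golden-section search for the minimum of a unimodal f on [lo, hi]."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def refit_signatures(
    counts: np.ndarray,
    catalog: SignatureCatalog,
    tol: float = 1e-6,
    max_sweeps: int = 1000,
) -> SignatureFit:
    """Refit absolute signature contributions to a context count vector.

    Cyclic coordinate descent; each coordinate is optimised by
    golden-section line search on [0, sum(counts)].  Stops when the
    objective improves by less than ``tol`` (relative to max(1, objective))
    over a full sweep.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(catalog.context_keys),):
        raise ValueError("counts length does not match catalog context keys")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n_sig = len(catalog)
    total = counts.sum()
    contrib = np.zeros(n_sig)
    if total == 0:
        return SignatureFit(list(catalog.names), contrib, 0.0, 0.0)

    P = catalog.profiles  # (n_sig, n_ctx)
    sq_norms = np.einsum("ij,ij->i", P, P)
    residual = counts.copy()  # counts - P.T @ contrib
    obj = float(residual @ residual)
    line_tol = max(total, 1.0) * 1e-10
    for _ in range(max_sweeps):
        prev = obj
        for j in range(n_sig):
            if sq_norms[j] == 0:
                continue
            pj = P[j]
            # residual without signature j's current contribution
            base = residual + contrib[j] * pj
            a_cross = float(pj @ base)

            def f(c, a2=sq_norms[j], ax=a_cross):
                return a2 * c * c - 2.0 * ax * c

            new_c = _golden_section_min(f, 0.0, total, line_tol)
            if new_c < line_tol:
                new_c = 0.0
            residual = base - new_c * pj
            contrib[j] = new_c
        obj = float(residual @ residual)
        if prev - obj <= tol * max(1.0, obj):
            break
    recon = P.T @ contrib
    return SignatureFit(
        list(catalog.names),
        contrib,
        _cosine(counts, recon),
        obj,
    )


def signature_similarity(fit_a: SignatureFit, fit_b: SignatureFit) -> float:
    """Cosine similarity of relative contribution vectors (0 for zero fits)."""
    if fit_a.names != fit_b.names:
        raise ValueError("fits cover different signature sets")
    return _cosine(fit_a.relative(), fit_b.relative())


def select_signatures(
    cohort_counts: dict[str, np.ndarray],
    catalog: SignatureCatalog,
    min_contrib_frac: float = 0.05,
    min_sample_frac: float = 0.10,
    max_iters: int = 8,
) -> SignatureCatalog:
    """Select signatures that contribute consistently across a cohort.

    All samples are refit with the full catalog, signatures are ranked by
    summed absolute contribution, refits are repeated with shrinking
    top-k subsets, and a signature is retained only if, in every run where
    it appears, it contributes at least ``min_contrib_frac`` of the
    mutations in at least ``min_sample_frac`` of the samples.
    """
    if len(cohort_counts) < 2:
        raise ValueError("signature selection requires at least 2 samples")
    samples = list(cohort_counts)
    totals = {s: max(float(np.sum(cohort_counts[s])), 1.0) for s in samples}

    def consistent(sub: SignatureCatalog) -> dict[str, bool]:
        hits = {name: 0 for name in sub.names}
        for s in samples:
            fit = refit_signatures(cohort_counts[s], sub)
            for name, c in zip(fit.names, fit.contributions):
                if c >= min_contrib_frac * totals[s]:
                    hits[name] += 1
        need = min_sample_frac * len(samples)
        return {name: hits[name] >= need for name in sub.names}

    # rank by summed contribution under the full catalog
    summed = np.zeros(len(catalog))
    for s in samples:
        summed += refit_signatures(cohort_counts[s], catalog).contributions
    order = [catalog.names[i] for i in np.argsort(-summed, kind="stable")]

    ok = {name: True for name in catalog.names}
    ks = sorted(
        {max(1, round(len(catalog) * (1 - i / max_iters))) for i in range(max_iters)},
        reverse=True,
    )
    for k in ks:
        sub = catalog.subset(order[:k])
        for name, good in consistent(sub).items():
            ok[name] = ok[name] and good
    selected = [n for n in catalog.names if ok[n]]
    if not selected:
        raise ValueError(
            "no signature passed the consistency thresholds; "
            "lower min_contrib_frac or min_sample_frac"
        )
    return catalog.subset(selected)


def contribution_table(
    fits: dict[str, SignatureFit]
) -> pd.DataFrame:
    """Per-sample absolute contribution table (samples x signatures)."""
    return pd.DataFrame({s: f.as_dict() for s, f in fits.items()}).T
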