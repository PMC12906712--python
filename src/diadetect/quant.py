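"""maxLFQ protein quantification from precursor quantities.

The maxLFQ scheme estimates a relative protein abundance profile across
samples by (1) taking, for every pair of samples, the median log2 ratio
over precursors quantified in both, and (2) solving the least-squares
system ``x_i - x_j ≈ r_ij`` for the per-sample log2 abundances.  Samples
connected by no shared precursor form separate components that are
anchored independently; the anchor sets each component's mean log2
abundance to the mean log2 of its observed precursor quantities, so a
single-precursor protein reproduces that precursor's profile exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def pairwise_log_ratios(log_quants: np.ndarray, min_shared: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Median pairwise log2 ratios between samples for one protein.

    Parameters
    ----------
    log_quants : ndarray, shape (n_precursors, n_samples)
        log2 precursor quantities, NaN where not quantified.
    min_shared : int
        Minimum number of precursors quantified in both samples for the
        ratio to be defined (default 1; DIA-NN-like).

    Returns
    -------
    ratios : ndarray, shape (n_samples, n_samples)
        ``ratios[i, j]`` = median over shared precursors of
        ``log2(q_i) - log2(q_j)``; NaN where fewer than ``min_shared``
        precursors are shared.  Antisymmetric where defined.
    support : ndarray of int, same shape
        Number of shared precursors behind each entry.
    """
    log_quants = np.asarray(log_quants, dtype=float)
    if log_quants.ndim != 2 or log_quants.shape[0] < 1:
        raise ValueError("log_quants must be a (precursors x samples) matrix with >= 1 precursor")
    n_samples = log_quants.shape[1]
    ratios = np.full((n_samples, n_samples), np.nan)
    support = np.zeros((n_samples, n_samples), dtype=int)
    observed = ~np.isnan(log_quants)
    for i in range(n_samples):
        ratios[i, i] = 0.0
        support[i, i] = int(observed[:, i].sum())
        for j in range(i + 1, n_samples):
            shared = observed[:, i] & observed[:, j]
            count = int(shared.sum())
            support[i, j] = support[j, i] = count
            if count >= min_shared and count > 0:
                # even-length medians: mean of the two central values (np.median default)
                med = float(np.median(log_quants[shared, i] - log_quants[shared, j]))
                ratios[i, j] = med
                ratios[j, i] = -med
    return ratios, support


def _components(ratios: np.ndarray, has_data: np.ndarray) -> list[list[int]]:
    """Connected components of samples linked by defined off-diagonal ratios."""
    n = ratios.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps: list[list[int]] = []
    for start in range(n):
        if seen[start] or not has_data[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            node = stack.pop()
            comp.append(node)
            for other in range(n):
                if other != node and not seen[other] and has_data[other] and not np.isnan(ratios[node, other]):
                    seen[other] = True
                    stack.append(other)
        comps.append(sorted(comp))
    return comps


def solve_profile(ratios: np.ndarray, log_quants: np.ndarray) -> np.ndarray:
    """Least-squares log2 abundance profile from a pairwise ratio matrix.

    Within each connected component the solution minimises
    ``sum (x_i - x_j - r_ij)^2`` over defined pairs, then is shifted so
    the component's mean log2 abundance equals the mean of the observed
    log2 precursor quantities in its samples.  Samples with no observed
    precursor are NaN.

    Parameters
    ----------
    ratios : (n_samples, n_samples) ndarray from :func:`pairwise_log_ratios`.
    log_quants : (n_precursors, n_samples) ndarray
        The log2 quantities the ratios were computed from (used for the
        anchoring means).

    Returns
    -------
    ndarray of shape (n_samples,) — log2 profile, NaN where undetermined.
    """
    log_quants = np.asarray(log_quants, dtype=float)
    n = ratios.shape[0]
    profile = np.full(n, np.nan)
    has_data = ~np.all(np.isnan(log_quants), axis=0)
    for comp in _components(ratios, has_data):
        idx = np.array(comp)
        k = len(idx)
        observed_vals = log_quants[:, idx]
        anchor = float(np.nanmean(observed_vals))
        if k == 1:
            profile[idx[0]] = anchor
            continue
        # normal equations for sum over defined pairs of (x_a - x_b - r)^2,
        # with a centering row to pin the gauge freedom
        A_rows, b_rows = [], []
        for a in range(k):
            for b in range(a + 1, k):
                r = ratios[idx[a], idx[b]]
                if np.isnan(r):
                    continue
                row = np.zeros(k)
                row[a], row[b] = 1.0, -1.0
                A_rows.append(row)
                b_rows.append(r)
        A = np.vstack(A_rows + [np.ones(k)])
        b = np.array(b_rows + [0.0])
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        profile[idx] = x - x.mean() + anchor
    return profile


def quantify_all(records: pd.DataFrame, meta: pd.DataFrame, min_shared: int = 1) -> pd.DataFrame:
    """Aggregate filtered precursor records to a protein × sample matrix.

    Zero, negative or missing quantities are treated as missing before
    the log transform.  Output is on the linear intensity scale with NaN
    for missing values; row order follows sorted protein groups, column
    order follows the metadata.

    Returns
    -------
    pandas.DataFrame
        Index = protein_group, columns = run_id, values = maxLFQ
        relative abundances (arbitrary intensity units).
    """
    runs = list(meta["run_id"])
    usable = records.loc[records["quantity"].notna() & (records["quantity"] > 0)]
    proteins = sorted(usable["protein_group"].unique())
    out = pd.DataFrame(np.nan, index=pd.Index(proteins, name="protein_group"), columns=runs)
    for protein, sub in usable.groupby("protein_group"):
        wide = sub.pivot(index="precursor_id", columns="run_id", values="quantity")
        wide = wide.reindex(columns=runs)
        log_q = np.log2(wide.to_numpy(dtype=float))
        ratios, _ = pairwise_log_ratios(log_q, min_shared=min_shared)
        profile = solve_profile(ratios, log_q)
        out.loc[protein] = np.exp2(profile)
    return out
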