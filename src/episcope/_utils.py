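"""Small shared helpers: FDR, interval overlap, seeded RNG spawning."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pyranges as pr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("episcope")

AUTOSOME_EXCLUDE = {"chrX", "chrY", "chrM", "X", "Y", "M", "MT", "chrMT"}


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg q-values; NaN p-values propagate to NaN q."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def as_pyranges(df: pd.DataFrame, chrom="chrom", start="start", end="end") -> pr.PyRanges:
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": df[chrom].astype(str),
                "Start": df[start].astype(int),
                "End": df[end].astype(int),
                "_idx": np.arange(len(df)),
            }
        )
    )


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame, **cols) -> np.ndarray:
    """Boolean mask over `query` rows: does the interval overlap any subject
    interval by >= 1 bp (bedtools-intersect semantics)? Intervals are 0-based
    half-open with columns chrom/start/end unless overridden via **cols."""
    mask = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or subject is None or len(subject) == 0:
        return mask
    q = as_pyranges(query, **cols)
    s = as_pyranges(subject, **cols)
    hit = q.overlap(s)
    if len(hit) > 0:
        mask[hit.df["_idx"].to_numpy()] = True
    return mask


def spawn_rng(seed, *key) -> np.random.Generator:
    """Derive an independent Generator from (seed, key...) deterministically.

    String keys are hashed with crc32 so the stream does not depend on
    PYTHONHASHSEED.
    """
    import zlib

    parts = [int(seed) % (2**31)]
    for k in key:
        if isinstance(k, str):
            parts.append(zlib.crc32(k.encode()) % (2**31))
        else:
            parts.append(int(k) % (2**31))
    return np.random.default_rng(np.random.SeedSequence(parts))
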