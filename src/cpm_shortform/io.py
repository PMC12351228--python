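"""CSV formats for responses, covariates and item metadata.

Responses: header ``person_id,A1,...,B12``; cells 0/1, empty = missing.
Covariates: ``person_id,bds,htks,crvt,ran_ies``; empty = missing.
Item metadata: ``item_id,set_label,domain_label,is_practice,target_p``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .items import ITEM_IDS, PRACTICE_ITEMS

logger = logging.getLogger(__name__)

__all__ = [
    "read_response_csv",
    "write_response_csv",
    "read_covariates_csv",
    "write_covariates_csv",
    "write_item_metadata_csv",
]


def write_response_csv(responses: pd.DataFrame, path) -> None:
    """Write a persons x items response matrix (empty cell = missing)."""
    out = responses.copy()
    out.index.name = "person_id"
    out.to_csv(path, na_rep="")


def read_response_csv(path, drop_practice: bool = True) -> pd.DataFrame:
    """Read and validate a response matrix.

    Cells must be 0, 1 or empty (missing -> NaN). Practice items A1/A2 are
    dropped by default with a log notice. Duplicate person ids and unknown
    values raise.
    """
    df = pd.read_csv(path, index_col="person_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate person_id(s): {dupes}")
    for col in df.columns:
        values = df[col]
        bad = ~(values.isna() | values.isin([0, 1]))
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-binary cell at person_id={row}, item={col!r}"
            )
    df = df.astype(float)
    if drop_practice:
        present = [c for c in PRACTICE_ITEMS if c in df.columns]
        if present:
            logger.info("dropping practice item(s) %s", present)
            df = df.drop(columns=present)
    logger.info("read responses: %d persons x %d items", *df.shape)
    return df


def write_covariates_csv(covariates: pd.DataFrame, path) -> None:
    out = covariates.copy()
    out.index.name = "person_id"
    out.to_csv(path, na_rep="")


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="person_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate person_id(s) in covariate table")
    return df.astype(float)


def write_item_metadata_csv(item_params, path) -> None:
    """Write per-item metadata (and 2PL parameters when present)."""
    rows = []
    for ip in item_params:
        rows.append(
            {
                "item_id": ip.item_id,
                "set_label": ip.set_label,
                "domain_label": ip.domain_label,
                "is_practice": ip.is_practice,
                "target_p": ip.target_p,
                "difficulty": ip.difficulty,
                "discrimination": ip.discrimination,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
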