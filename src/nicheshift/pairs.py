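"""Labeling sister pairs by niche difference and assembling the age dataset.

The resulting table — one row per terminal sister pair with a relative
split age in [0, 1] and a binary niche-difference label (1 = different
hosts and/or larval feeding habits, 0 = identical or overlapping niches)
— is the input to the age-corrected logistic regression.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .niche import NicheCoding, niches_differ
from .treeio import SisterPair

logger = logging.getLogger(__name__)

__all__ = ["classify_pairs", "proportion_different", "read_pair_table", "write_pair_table"]

PAIR_COLUMNS = ["tip_a", "tip_b", "split_age", "niche_different"]


def classify_pairs(
    pairs: Iterable[SisterPair], coding: NicheCoding
) -> pd.DataFrame:
    """Label each sister pair as niche-different (1) or overlapping (0).

    Pairs in which either member has an unknown niche (outgroups) or is
    absent from the coding are dropped with a warning; a species paired
    with itself (duplicate exemplars of one species) is labeled 0 only if
    kept, but such pairs are collapsed out here as uninformative.

    Raises ``ValueError`` when no classifiable pair remains.
    """
    rows = []
    for pair in pairs:
        if pair.tip_a == pair.tip_b:
            logger.warning("dropping self-pair %s", pair.tip_a)
            continue
        a = coding.state_of(pair.tip_a)
        b = coding.state_of(pair.tip_b)
        if a is None or b is None:
            logger.warning(
                "dropping pair (%s, %s): niche unknown for one or both members",
                pair.tip_a, pair.tip_b,
            )
            continue
        rows.append(
            {
                "tip_a": pair.tip_a,
                "tip_b": pair.tip_b,
                "split_age": float(pair.split_age),
                "niche_different": int(niches_differ(a, b)),
            }
        )
    if not rows:
        raise ValueError("no classifiable sister pairs; regression impossible")
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    logger.info(
        "classified %d pairs: %d niche-different, %d overlapping",
        len(df), int(df.niche_different.sum()), int((1 - df.niche_different).sum()),
    )
    return df


def proportion_different(dataset: pd.DataFrame) -> tuple[float, float]:
    """Raw fraction of niche-different pairs and the percentage (1 decimal)."""
    n = len(dataset)
    if n == 0:
        raise ValueError("empty pair dataset")
    frac = float(dataset["niche_different"].sum()) / n
    return frac, round(100.0 * frac, 1)


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PAIR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    return df


def write_pair_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
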