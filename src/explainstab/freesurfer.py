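"""Readers for FreeSurfer tabular stats exports.

`aparcstats2table` / `asegstats2table` emit tab-separated tables with one row
per subject: the first column is the subject id (its header names the
measure, e.g. ``lh.aparc.thickness``), the remaining columns are numeric
per-region measures.  Several such tables (thickness, area, curvature,
volumes...) are merged column-wise on subject id to build the cohort feature
matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["parse_freesurfer_stats_table", "merge_stats_tables"]


class StatsTableError(ValueError):
    pass


def parse_freesurfer_stats_table(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse one stats table.

    Returns ``(subject_ids, feature_names, matrix)`` with subjects in file
    order and the id column's header dropped from the feature names.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise StatsTableError(f"{path}: expected an id column plus measures")
    ids = df.iloc[:, 0].astype(str).to_numpy()
    if len(set(ids)) != len(ids):
        raise StatsTableError(f"{path}: duplicate subject ids")
    names = df.columns[1:].to_numpy(dtype=str)
    matrix = np.empty((len(ids), len(names)))
    for j, col in enumerate(df.columns[1:]):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise StatsTableError(f"{path}: non-numeric value in column {col!r}")
        matrix[:, j] = vals
    return ids, names, matrix


def merge_stats_tables(paths) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge several stats tables column-wise, aligned on subject id.

    Row order follows the first table.  Every table must cover exactly the
    same subjects; ids present in one table and absent in another raise an
    error listing them.
    """
    parsed = [parse_freesurfer_stats_table(p) for p in paths]
    if not parsed:
        raise StatsTableError("no tables to merge")
    ref_ids = parsed[0][0]
    ref_set = set(ref_ids)
    for (ids, _, _), path in zip(parsed[1:], list(paths)[1:]):
        here = set(ids)
        if here != ref_set:
            missing = sorted(ref_set - here) + sorted(here - ref_set)
            raise StatsTableError(f"{path}: subject set mismatch, differing ids {missing}")
    blocks, names = [], []
    for ids, cols, matrix in parsed:
        order = {s: i for i, s in enumerate(ids)}
        rows = np.asarray([order[s] for s in ref_ids])
        blocks.append(matrix[rows])
        names.append(cols)
    return ref_ids, np.concatenate(names), np.concatenate(blocks, axis=1)
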