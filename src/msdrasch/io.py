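"""CSV/JSON readers and writers for rating matrices and fit results.

File conventions: rating matrices are CSV with persons as rows (first
column person IDs), items as columns (header row of item IDs), ratings as
integers 0..L, and missing cells empty or equal to a configurable token
(default ``NA``).  Fit results go to ``persons.csv``, ``items.csv`` and
``thresholds.csv`` plus a JSON summary; every output directory gets a
``run.json`` recording the configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from .andrich import AndrichFit
from .data import RatingMatrix
from .msd import MSDFit

__all__ = [
    "RunConfig",
    "read_rating_csv",
    "write_rating_csv",
    "write_fit_tables",
    "write_run_json",
]


def _pkg_version() -> str:
    try:
        return version("msdrasch")
    except PackageNotFoundError:
        return "unknown"


@dataclass
class RunConfig:
    """Settings of one CLI run, serialized to run.json for reproducibility."""

    command: str
    input_path: str | None = None
    output_dir: str | None = None
    missing_token: str = "NA"
    model: str = "msd"
    tolerance: float = 1e-6
    seed: int | None = None
    se_divisor: str = "L"
    merge_rule: str = "most_disordered"
    one_based: bool = False


def read_rating_csv(
    path,
    missing_token: str = "NA",
    max_category: int | None = None,
    one_based: bool = False,
) -> RatingMatrix:
    """Read a persons-by-items rating CSV into a :class:`RatingMatrix`.

    ``one_based`` shifts 1..L+1 coded files down to the 0..L convention.
    Non-integer or negative cells raise with the offending row and column.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    person_ids = [str(i) for i in df.index]
    item_ids = [str(c) for c in df.columns]
    mat = np.full(df.shape, np.nan)
    for jj, col in enumerate(df.columns):
        for ii, cell in enumerate(df[col].to_numpy()):
            cell = cell.strip()
            if cell == "" or cell == missing_token:
                continue
            try:
                val = int(cell)
            except ValueError:
                raise ValueError(
                    f"non-integer rating {cell!r} at row {person_ids[ii]!r}, "
                    f"column {item_ids[jj]!r}"
                ) from None
            mat[ii, jj] = val
    if one_based:
        mat = mat - 1
    obs = ~np.isnan(mat)
    if obs.any() and mat[obs].min() < 0:
        bad = np.argwhere(obs & (mat < 0))[0]
        raise ValueError(
            f"rating below 0 at row {person_ids[bad[0]]!r}, "
            f"column {item_ids[bad[1]]!r}"
        )
    return RatingMatrix(
        ratings=mat,
        max_category=max_category,
        person_ids=person_ids,
        item_ids=item_ids,
    )


def write_rating_csv(R: RatingMatrix, path, missing_token: str = "NA") -> None:
    df = pd.DataFrame(R.ratings, index=R.person_ids, columns=R.item_ids)
    txt = df.map(lambda v: missing_token if np.isnan(v) else str(int(v)))
    txt.index.name = "person"
    txt.to_csv(path)


def _table(ids, est, se, n_obs, infit=None) -> pd.DataFrame:
    d = {"id": ids, "estimate": est, "se": se, "n_obs": n_obs}
    d["infit"] = infit if infit is not None else np.nan
    return pd.DataFrame(d)


def write_fit_tables(
    fit, R: RatingMatrix, outdir, infit_report=None
) -> None:
    """Write persons.csv, items.csv, thresholds.csv and summary.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_obs_p = R.observed.sum(axis=1)
    n_obs_i = R.observed.sum(axis=0)
    pi = infit_report.person_infit if infit_report is not None else None
    ii = infit_report.item_infit if infit_report is not None else None
    _table(R.person_ids, fit.person_measures, fit.person_se, n_obs_p, pi).to_csv(
        outdir / "persons.csv", index=False
    )
    _table(R.item_ids, fit.item_measures, fit.item_se, n_obs_i, ii).to_csv(
        outdir / "items.csv", index=False
    )
    tdf = pd.DataFrame(
        {
            "id": [f"tau_{h}" for h in range(1, fit.thresholds.size + 1)],
            "estimate": fit.thresholds,
            "se": fit.threshold_se,
        }
    )
    if isinstance(fit, AndrichFit):
        flags = np.concatenate([fit.disorder_flags, [False]])
        tdf["disordered_with_next"] = flags
    tdf.to_csv(outdir / "thresholds.csv", index=False)
    summary: dict = {
        "model": "andrich" if isinstance(fit, AndrichFit) else "msd",
        "n_persons": R.n_persons,
        "n_items": R.n_items,
        "n_thresholds": int(fit.thresholds.size),
    }
    if isinstance(fit, MSDFit):
        summary["dichotomizations"] = [
            {
                "level": f.level,
                "iterations": f.n_iterations,
                "max_score_residual": f.max_score_residual,
                "excluded_persons": f.excluded_persons.tolist(),
                "excluded_items": f.excluded_items.tolist(),
            }
            for f in fit.dichotomous_fits
        ]
    else:
        summary["iterations"] = fit.n_iterations
        summary["disordered_pairs"] = int(fit.disorder_flags.sum())
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def write_run_json(config: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = asdict(config)
    payload["msdrasch_version"] = _pkg_version()
    payload["numpy_version"] = np.__version__
    (outdir / "run.json").write_text(json.dumps(payload, indent=2))
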