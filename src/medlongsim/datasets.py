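"""Simulated longitudinal cohorts and their on-disk representation.

One :class:`TrialDataset` is a complete cohort: per subject a continuous
covariate ``z1``, a binary exposure ``z2``, a baseline mediator ``x`` and
six repeated outcomes at fixed times.  Generation follows the structural
model: draw covariates, draw the three structural residuals with
covariance Psi (non-normal per the error spec, intermediate-correlation
preserving), solve for the latents, draw iid measurement residuals and
form the outcomes.  No missingness is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .distributions import ErrorSpec, draw_errors
from .parameters import SEMParameters

__all__ = ["TrialDataset", "simulate_dataset", "write_dataset", "read_dataset"]

LONG_COLUMNS = ["subject_id", "time", "y", "x", "z1", "z2"]


@dataclass
class TrialDataset:
    """One simulated cohort in wide (one row per subject) layout."""

    z1: np.ndarray
    z2: np.ndarray
    x: np.ndarray
    y: np.ndarray  # (n, 6)
    times: np.ndarray
    params: SEMParameters | None = None
    error_spec: ErrorSpec | None = None
    seed: int | None = None
    subject_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z1 = np.asarray(self.z1, dtype=float)
        self.z2 = np.asarray(self.z2, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        n = self.z1.shape[0]
        if self.subject_id is None:
            self.subject_id = np.arange(1, n + 1)
        if not (self.z2.shape[0] == self.x.shape[0] == self.y.shape[0] == n):
            raise ValueError("inconsistent subject counts")
        if self.y.shape != (n, 6):
            raise ValueError("y must be (n_subjects, 6)")
        if not np.all(np.isin(self.z2, (0.0, 1.0))):
            raise ValueError("z2 must be binary 0/1")

    @property
    def n_subjects(self) -> int:
        return int(self.z1.shape[0])

    def to_long(self) -> pd.DataFrame:
        n = self.n_subjects
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_id, 6),
                "time": np.tile(self.times, n),
                "y": self.y.ravel(),
                "x": np.repeat(self.x, 6),
                "z1": np.repeat(self.z1, 6),
                "z2": np.repeat(self.z2, 6),
            }
        )

    def to_wide(self) -> pd.DataFrame:
        d = {"subject_id": self.subject_id, "z1": self.z1,
             "z2": self.z2, "x": self.x}
        for j in range(6):
            d[f"y{j + 1}"] = self.y[:, j]
        df = pd.DataFrame(d)
        return df

    @classmethod
    def from_long(cls, df: pd.DataFrame, **meta) -> "TrialDataset":
        missing = set(LONG_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"malformed long table, missing columns {sorted(missing)}")
        if df.duplicated(["subject_id", "time"]).any():
            raise ValueError("duplicated (subject_id, time) keys")
        df = df.sort_values(["subject_id", "time"], kind="stable")
        times = np.sort(df["time"].unique())
        if times.size != 6:
            raise ValueError(f"expected 6 measurement times, found {times.size}")
        wide = df.pivot(index="subject_id", columns="time", values="y")
        per = df.groupby("subject_id")[["x", "z1", "z2"]].first()
        if (df.groupby("subject_id")[["x", "z1", "z2"]].nunique() > 1).any().any():
            raise ValueError("x, z1, z2 must be constant within subject")
        return cls(
            z1=per["z1"].to_numpy(), z2=per["z2"].to_numpy(),
            x=per["x"].to_numpy(), y=wide.to_numpy(),
            times=times, subject_id=per.index.to_numpy(), **meta,
        )

    @classmethod
    def from_wide(cls, df: pd.DataFrame, times: np.ndarray, **meta) -> "TrialDataset":
        ycols = [f"y{j + 1}" for j in range(6)]
        missing = {"subject_id", "z1", "z2", "x", *ycols} - set(df.columns)
        if missing:
            raise ValueError(f"malformed wide table, missing columns {sorted(missing)}")
        return cls(
            z1=df["z1"].to_numpy(), z2=df["z2"].to_numpy(),
            x=df["x"].to_numpy(), y=df[ycols].to_numpy(),
            times=np.asarray(times, dtype=float),
            subject_id=df["subject_id"].to_numpy(), **meta,
        )


def simulate_dataset(
    params: SEMParameters,
    n: int,
    errors: ErrorSpec | None = None,
    seed: int = 0,
) -> TrialDataset:
    """Generate one cohort of ``n`` subjects from the mediated growth model.

    Sub-streams for (covariates, structural residuals, measurement
    residuals) are spawned deterministically from the root seed so that,
    e.g., changing the effect split leaves the covariate draws untouched.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    errors = errors or ErrorSpec()
    ss = np.random.SeedSequence(seed)
    rng_z, rng_zeta, rng_eps = (np.random.default_rng(s) for s in ss.spawn(3))

    z1 = rng_z.standard_normal(n)
    z2 = (rng_z.random(n) < params.z2_prev).astype(float)

    struct_spec = errors if errors.structural_is_nonnormal() else ErrorSpec(
        family="normal", level=errors.level)
    zeta = draw_errors(struct_spec, n, params.psi, rng_zeta,
                       stream="structural")

    # solve the (recursive) structural model: U3 first, then U1, U2
    Z = np.column_stack([z1, z2])
    U3 = params.alpha3 + Z @ params.Gamma[2] + zeta[:, 2]
    U1 = params.alpha1 + Z @ params.Gamma[0] + params.b13 * U3 + zeta[:, 0]
    U2 = params.alpha2 + Z @ params.Gamma[1] + params.b23 * U3 + zeta[:, 1]

    meas_spec = errors if errors.family != "normal" else ErrorSpec(
        family="normal", level=errors.level)
    eps = draw_errors(meas_spec, n, params.sigma2 * np.eye(6), rng_eps,
                      stream="measurement")

    y = U1[:, None] + np.outer(U2, params.times) + eps
    return TrialDataset(z1=z1, z2=z2, x=U3, y=y, times=params.times,
                        params=params, error_spec=errors, seed=seed)


def write_dataset(
    ds: TrialDataset,
    path: str | Path,
    layout: Literal["long", "wide"] = "long",
) -> None:
    """Write a cohort to CSV with a JSON provenance sidecar (.meta.json)."""
    path = Path(path)
    df = ds.to_long() if layout == "long" else ds.to_wide()
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "layout": layout,
        "times": ds.times.tolist(),
        "seed": ds.seed,
        "params": ds.params.to_dict() if ds.params is not None else None,
        "error_spec": ds.error_spec.to_dict() if ds.error_spec else None,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2))


def read_dataset(
    path: str | Path,
    layout: Literal["long", "wide"] = "long",
) -> TrialDataset:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta: dict = {}
    if meta_path.exists():
        raw = json.loads(meta_path.read_text())
        if raw.get("params"):
            meta["params"] = SEMParameters.from_dict(raw["params"])
        if raw.get("error_spec"):
            meta["error_spec"] = ErrorSpec.from_dict(raw["error_spec"])
        meta["seed"] = raw.get("seed")
    if layout == "long":
        return TrialDataset.from_long(df, **meta)
    raw_meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    times = np.asarray(raw_meta.get("times", np.arange(6.0)), dtype=float)
    return TrialDataset.from_wide(df, times=times, **meta)
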