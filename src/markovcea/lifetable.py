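"""Period life tables: loading, validation, lookup and residual life expectancy.

A :class:`LifeTable` holds one annual death probability ``qx`` per integer
age.  It provides the age-dependent background mortality used by the cohort
model and the life-expectancy computation used for model validation.

Tables use *period* semantics: a subject aged ``a`` at cycle ``t`` is
exposed to the tabulated ``qx`` at age ``a + t``, i.e. calendar-year
mortality is applied along the diagonal with no cohort projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "LifeTableError", "load_life_table", "default_life_table"]

#: Age at which tables are closed (qx forced to 1) when no closure row exists.
DEFAULT_TERMINAL_AGE = 110

_BUNDLED_TABLE = "fr_male_2017_standin.csv"


class LifeTableError(ValueError):
    """Raised when a life table violates its structural invariants."""


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities indexed by contiguous integer ages.

    Parameters
    ----------
    ages
        Strictly increasing, contiguous integer ages.
    qx
        Probability of dying within ``[age, age + 1)``; each in ``[0, 1]``,
        and exactly 1 at the terminal age.
    """

    ages: np.ndarray
    qx: np.ndarray
    terminal_age: int = field(init=False)

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise LifeTableError("ages and qx must be equal-length 1-d arrays")
        diffs = np.diff(ages)
        if np.any(diffs != 1):
            bad = int(np.argmax(diffs != 1))
            raise LifeTableError(
                f"ages must be contiguous and strictly increasing; "
                f"offending row: age {ages[bad]} followed by {ages[bad + 1]}"
            )
        bad_q = np.where((qx < 0.0) | (qx > 1.0))[0]
        if bad_q.size:
            i = int(bad_q[0])
            raise LifeTableError(
                f"qx must lie in [0, 1]; offending row: age {ages[i]}, qx {qx[i]}"
            )
        if qx[-1] != 1.0:
            raise LifeTableError(
                f"table must close with qx = 1 at its last age ({ages[-1]})"
            )
        object.__setattr__(self, "terminal_age", int(ages[-1]))

    @property
    def start_age(self) -> int:
        return int(self.ages[0])

    def death_prob(self, age: float) -> float:
        """Annual death probability at ``floor(age)``.

        Ages beyond the terminal age return 1 (closure convention); ages
        below the first tabulated age are a domain error.
        """
        a = int(np.floor(age))
        if a < self.start_age:
            raise LifeTableError(
                f"age {age} is below the first tabulated age {self.start_age}"
            )
        if a > self.terminal_age:
            return 1.0
        return float(self.qx[a - self.start_age])

    def survival(self, age: int) -> np.ndarray:
        """``S(k)``: probability of surviving ``k`` full years from ``age``."""
        a = int(age)
        if not self.start_age <= a <= self.terminal_age:
            raise LifeTableError(f"age {age} outside table range")
        return np.cumprod(1.0 - self.qx[a - self.start_age :])

    def life_expectancy(self, age: int, half_cycle: bool = True) -> float:
        """Residual life expectancy ``e(age) = sum_k S(k) (+ 0.5)``.

        The optional half-year term (default on) is the usual continuity
        correction crediting the average part-year lived in the year of
        death.
        """
        e = float(self.survival(age).sum())
        return e + 0.5 if half_cycle else e

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def write(self, path: Union[str, Path], sep: str = ",") -> None:
        # %.17g guarantees bit-exact float round-trips through text
        self.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def _validated_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    cols = {c.lower().strip(): c for c in df.columns}
    if "age" not in cols or "qx" not in cols:
        raise LifeTableError(
            f"{source}: expected columns 'age' and 'qx', found {list(df.columns)}"
        )
    out = df[[cols["age"], cols["qx"]]].copy()
    out.columns = ["age", "qx"]
    for col in ("age", "qx"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        if coerced.isna().any():
            row = int(np.argmax(coerced.isna().to_numpy()))
            raise LifeTableError(
                f"{source}: non-numeric {col!r} value {out[col].iloc[row]!r} "
                f"at data row {row}"
            )
        out[col] = coerced
    if out["age"].duplicated().any():
        dup = int(out.loc[out["age"].duplicated(), "age"].iloc[0])
        raise LifeTableError(f"{source}: duplicate age {dup}")
    return out.sort_values("age").reset_index(drop=True)


def load_life_table(
    path: Union[str, Path],
    terminal_age: int = DEFAULT_TERMINAL_AGE,
) -> LifeTable:
    """Read a delimited life table (columns ``age`` and ``qx``).

    Comma- and tab-separated files are accepted.  Extra metadata columns
    (e.g. ``year``, ``sex``) are ignored.  If the table does not close with
    ``qx = 1``, a closure row is appended at ``terminal_age`` (or at the
    next age when the table already extends that far).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"life table file not found: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip parsing keeps qx bit-identical through write/read cycles
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    frame = _validated_frame(df, str(path))
    ages = frame["age"].to_numpy(dtype=float)
    if np.any(ages != np.floor(ages)):
        i = int(np.argmax(ages != np.floor(ages)))
        raise LifeTableError(f"{path}: non-integer age {ages[i]} at data row {i}")
    ages = ages.astype(int)
    qx = frame["qx"].to_numpy(dtype=float)
    if qx[-1] != 1.0:
        close_at = max(terminal_age, int(ages[-1]) + 1)
        pad_ages = np.arange(ages[-1] + 1, close_at + 1)
        # carry the last observed qx forward, then force closure
        pad_qx = np.full(pad_ages.shape, qx[-1])
        ages = np.concatenate([ages, pad_ages])
        qx = np.concatenate([qx, pad_qx])
        qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def default_life_table() -> LifeTable:
    """Bundled stand-in for the French male 2017 period table.

    A Gompertz–Makeham table calibrated to published 2017 French male
    summary statistics (life expectancy 79.4 at birth, 23.2 at age 60);
    see the package data directory for provenance notes.
    """
    with resources.as_file(
        resources.files("markovcea.data").joinpath(_BUNDLED_TABLE)
    ) as p:
        return load_life_table(p)
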