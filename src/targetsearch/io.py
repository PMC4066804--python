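"""CSV/JSON input–output with mandatory unit suffixes.

The experimental tables mix nM, uM, M, bp and 10^8 M^-1 s^-1; silent
unit mistakes are the main hazard of this kind of pipeline.  Every CSV
column header therefore carries its unit as a suffix
(``time_s``, ``P_tot_nM``, ``k_a_1e8_per_M_per_s`` ...) and loading
normalises to the internal units (molar, bp, seconds) exactly.

Run configuration is a strict pydantic model (unknown keys rejected)
that also houses the fixed per-site nonspecific K_d,N table by KCl.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .fitting import RateDataset
from .ionic import PowerLaw
from .model import AssayCondition
from .traces import KineticTrace, TitrationSeries

__all__ = [
    "RunConfig",
    "UNIT_FACTORS",
    "load_trace",
    "load_titration",
    "load_rate_dataset",
    "save_rate_dataset",
    "save_laws",
    "load_laws",
    "config_hash",
]

log = logging.getLogger("targetsearch")

# Multiplicative factor taking a suffixed column to internal units
# (M, bp, s, M^-1 s^-1).  Longest suffixes must be matched first.
UNIT_FACTORS: Dict[str, float] = {
    "1e8_per_M_per_s": 1e8,
    "per_M_per_s": 1.0,
    "per_s": 1.0,
    "nM": 1e-9,
    "uM": 1e-6,
    "mM": 1e-3,
    "M": 1.0,
    "ms": 1e-3,
    "s": 1.0,
    "bp": 1.0,
    "sites": 1.0,
    "au": 1.0,  # arbitrary (fluorescence) units
}


class RunConfig(BaseModel):
    """Conventions, fixed constants and flags shared across a run."""

    model_config = ConfigDict(extra="forbid")

    footprint_B: int = 9
    target_pos_m: int = 2
    phi: int = 2
    competitor_len_bp: int = 28
    probe_len_bp: int = 113
    D_tot_M: float = 2.5e-9
    C_tot_M: float = 2e-6
    # Fixed per-site nonspecific K_d,N (M), keyed by KCl in mM.
    K_d_N_by_KCl_mM: Dict[float, float] = Field(
        default_factory=lambda: {
            40.0: 1.4e-6,
            60.0: 3.6e-6,
            80.0: 4.6e-6,
            110.0: 9.6e-6,
            150.0: 16e-6,
        }
    )
    allow_intercept: bool = True
    weighted: bool = False
    variant: str = "with_IT"
    seed: int = 0

    def K_d_N(self, KCl_mM: float) -> float:
        try:
            return self.K_d_N_by_KCl_mM[float(KCl_mM)]
        except KeyError:
            raise KeyError(
                f"no fixed K_d_N tabulated for {KCl_mM} mM KCl; "
                f"known: {sorted(self.K_d_N_by_KCl_mM)}"
            ) from None

    def condition(self, **overrides) -> AssayCondition:
        base = dict(
            probe_len_bp=self.probe_len_bp,
            competitor_len_bp=self.competitor_len_bp,
            D_tot=self.D_tot_M,
            C_tot=self.C_tot_M,
            footprint_B=self.footprint_B,
            target_pos_m=self.target_pos_m,
        )
        base.update(overrides)
        return AssayCondition(**base)


def config_hash(config: RunConfig) -> str:
    """Stable sha256 of the canonical JSON form of a config."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def split_unit(column: str) -> tuple[str, float]:
    """Split ``name_unit`` into (name, factor-to-internal-units)."""
    for suffix in UNIT_FACTORS:  # insertion order: longest first
        if column.endswith("_" + suffix):
            return column[: -(len(suffix) + 1)], UNIT_FACTORS[suffix]
    raise ValueError(
        f"column {column!r} lacks a recognised unit suffix "
        f"(one of {list(UNIT_FACTORS)})"
    )


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in df.columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, "
                f"row {int(bad[0]) + 2} of the file"
            )
    return df.astype(float)


def _normalised(path) -> Dict[str, np.ndarray]:
    df = _read_csv(path)
    out: Dict[str, np.ndarray] = {}
    for col in df.columns:
        name, factor = split_unit(col)
        out[name] = df[col].to_numpy() * factor
        if factor != 1.0:
            log.info("%s: converted %s by factor %g", path, col, factor)
    log.info("%s: %d rows", path, len(df))
    return out


def load_trace(path, label: str = "") -> KineticTrace:
    """Load a fluorescence trace CSV (columns time_s, intensity_*).

    The intensity column may carry any suffix; it is dimensionless for
    the fit, so only the time column is converted.
    """
    df = _read_csv(path)
    cols = {c: split_unit(c) for c in df.columns}
    tcol = [c for c, (n, _) in cols.items() if n == "time"]
    icol = [c for c, (n, _) in cols.items() if n == "intensity"]
    if not tcol or not icol:
        raise ValueError(f"{path}: need 'time_<unit>' and 'intensity_<unit>' columns")
    t = df[tcol[0]].to_numpy() * cols[tcol[0]][1]
    return KineticTrace(time=t, intensity=df[icol[0]].to_numpy(),
                        label=label or str(path))


def load_titration(path, label: str = "") -> TitrationSeries:
    """Load a titration CSV (P_tot_nM, k_app_per_s[, se_per_s])."""
    d = _normalised(path)
    if "P_tot" not in d or "k_app" not in d:
        raise ValueError(f"{path}: need P_tot and k_app columns")
    return TitrationSeries(
        P_tot=d["P_tot"], k_app=d["k_app"], se=d.get("se"),
        label=label or str(path),
    )


def load_rate_dataset(
    path, config: RunConfig, covariate_kind: str, KCl_mM: Optional[float] = None
) -> RateDataset:
    """Load a (covariate, k_a) CSV into internal units.

    The covariate column is ``length_bp``, ``C_tot_<conc>``,
    ``P_tot_<conc>`` or ``KCl_mM`` according to ``covariate_kind``;
    rate columns are ``k_a_...`` with an optional ``se_...``.  The
    fixed K_d,N is taken from the config table at ``KCl_mM`` (or the
    single tabulated value when the table has one entry).
    """
    cov_names = {
        "length": "length",
        "competitor": "C_tot",
        "protein": "P_tot",
        "KCl": "KCl",
    }
    if covariate_kind not in cov_names:
        raise ValueError(f"unknown covariate_kind {covariate_kind!r}")
    d = _normalised(path)
    name = cov_names[covariate_kind]
    if name not in d or "k_a" not in d:
        raise ValueError(f"{path}: need {name} and k_a columns")
    x = d[name]
    if covariate_kind == "KCl":
        x = x * 1e3  # KCl is carried in mM internally
    se = d.get("se")
    dup = len(x) != len(np.unique(x))
    if dup and se is None:
        raise ValueError(
            f"{path}: duplicate covariate values without per-point SEs"
        )
    if KCl_mM is None:
        if len(config.K_d_N_by_KCl_mM) != 1:
            raise ValueError("KCl_mM required to select K_d_N from the table")
        KCl_mM = next(iter(config.K_d_N_by_KCl_mM))
    return RateDataset(
        covariate_kind=covariate_kind,
        covariate=x,
        k_a=d["k_a"],
        se=se,
        condition=config.condition(KCl_mM=float(KCl_mM)),
        K_d_N=config.K_d_N(KCl_mM),
        metadata={"path": str(path), "KCl_mM": float(KCl_mM)},
    )


def save_rate_dataset(data: RateDataset, path) -> None:
    """Write a dataset back out in the suffixed-CSV dialect."""
    cov_col = {
        "length": ("length_bp", 1.0),
        "competitor": ("C_tot_uM", 1e6),
        "protein": ("P_tot_nM", 1e9),
        "KCl": ("KCl_mM", 1.0),
    }[data.covariate_kind]
    out = {cov_col[0]: data.covariate * cov_col[1],
           "k_a_per_M_per_s": data.k_a}
    if data.se is not None:
        out["se_per_M_per_s"] = data.se
    pd.DataFrame(out).to_csv(path, index=False)


def save_laws(laws: Dict[str, PowerLaw], path) -> None:
    """Serialise fitted power laws as JSON."""
    payload = {
        q: {"a": law.a, "b": law.b, "domain_mM": list(law.domain_mM)}
        for q, law in laws.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_laws(path) -> Dict[str, PowerLaw]:
    payload = json.loads(Path(path).read_text())
    return {
        q: PowerLaw(quantity=q, a=v["a"], b=v["b"],
                    domain_mM=tuple(v["domain_mM"]))
        for q, v in payload.items()
    }
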