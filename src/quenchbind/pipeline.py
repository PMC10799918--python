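"""End-to-end orchestration of the titration analysis.

``run_pipeline`` takes an :class:`AnalysisConfig` describing which input
files exist (per-temperature titration series, optional competitor series,
optional FRET spectra, optional synchronous scans) and runs every stage
those inputs support:

    inner-filter correction → Stern–Volmer → mechanism call →
    double-log binding → van't Hoff thermodynamics → displacement →
    FRET → synchronous peak shifts

Stages whose inputs are missing are skipped with a log message, never
silently defaulted.  The report is a plain dict (JSON-serializable, floats
at full repr precision); regeneration from identical inputs is
bit-identical apart from the timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Optional

from . import __version__
from .binding import BindingFit, displacement_analysis, double_log_fit
from .fret import fret_analysis
from .quenching import (
    DIFFUSION_LIMIT_M_S,
    TAU0_DEFAULT_S,
    classify_mechanism,
    stern_volmer_fit,
)
from .spectra import (
    SpectrumKind,
    TitrationSeries,
    ValidationError,
    intensity_at,
    load_titration,
    synchronous_shift,
)
from .thermo import vant_hoff

__all__ = ["AnalysisConfig", "run_pipeline", "load_config", "write_report"]

log = logging.getLogger("quenchbind.pipeline")


@dataclass(frozen=True)
class SeriesPaths:
    csv: str
    meta: str


@dataclass(frozen=True)
class FretInputs:
    donor_emission_csv: str
    donor_emission_meta: str
    acceptor_absorbance_csv: str
    acceptor_conc_M: float
    quenched_conc_M: float  # concentration at which F is read for E


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated pipeline configuration (paths checked at load time)."""

    series_by_temp: Mapping[float, SeriesPaths] = field(default_factory=dict)
    competitor_series: Mapping[str, SeriesPaths] = field(default_factory=dict)
    synchronous_series: Mapping[float, SeriesPaths] = field(default_factory=dict)
    fret: Optional[FretInputs] = None
    emission_nm: float = 340.0
    tau0_s: float = TAU0_DEFAULT_S
    diffusion_limit: float = DIFFUSION_LIMIT_M_S
    kappa2: float = 0.476
    phi_D: float = 0.15
    eta_inv4: float = 0.3139
    fret_window_nm: tuple[float, float] = (285.0, 450.0)
    displacement_threshold: float = 1.5

    def __post_init__(self) -> None:
        for v, name in (
            (self.tau0_s, "tau0_s"),
            (self.diffusion_limit, "diffusion_limit"),
            (self.kappa2, "kappa2"),
            (self.phi_D, "phi_D"),
            (self.eta_inv4, "eta_inv4"),
        ):
            if v <= 0:
                raise ValidationError(f"{name} must be positive")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an analysis config from JSON (YAML accepted by extension)."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    base = Path(path).parent

    def paths(entry: Mapping[str, str]) -> SeriesPaths:
        sp = SeriesPaths(str(base / entry["csv"]), str(base / entry["meta"]))
        for p in (sp.csv, sp.meta):
            if not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")
        return sp

    fret_cfg = None
    if raw.get("fret"):
        f = raw["fret"]
        fret_cfg = FretInputs(
            donor_emission_csv=str(base / f["donor_emission_csv"]),
            donor_emission_meta=str(base / f["donor_emission_meta"]),
            acceptor_absorbance_csv=str(base / f["acceptor_absorbance_csv"]),
            acceptor_conc_M=float(f["acceptor_conc_M"]),
            quenched_conc_M=float(f["quenched_conc_M"]),
        )
    return AnalysisConfig(
        series_by_temp={
            float(t): paths(entry) for t, entry in raw.get("series", {}).items()
        },
        competitor_series={
            str(name): paths(entry)
            for name, entry in raw.get("competitor_series", {}).items()
        },
        synchronous_series={
            float(off): paths(entry)
            for off, entry in raw.get("synchronous_series", {}).items()
        },
        fret=fret_cfg,
        emission_nm=float(raw.get("emission_nm", 340.0)),
        tau0_s=float(raw.get("tau0_ns", TAU0_DEFAULT_S * 1e9)) * 1e-9,
        diffusion_limit=float(raw.get("diffusion_limit", DIFFUSION_LIMIT_M_S)),
        kappa2=float(raw.get("kappa2", 0.476)),
        phi_D=float(raw.get("phi_D", 0.15)),
        eta_inv4=float(raw.get("eta_inv4", 0.3139)),
        fret_window_nm=tuple(raw.get("fret_window_nm", (285.0, 450.0))),
        displacement_threshold=float(raw.get("displacement_threshold", 1.5)),
    )


def _asdict(obj: Any) -> Any:
    import numpy as np

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, Mapping):
        return {str(k): _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


def _conc_index(concs, target: float, name: str) -> int:
    """Index of a concentration in a series, tolerant to float formatting."""
    import numpy as np

    arr = np.asarray(concs, dtype=float)
    idx = int(np.argmin(np.abs(arr - target)))
    if not np.isclose(arr[idx], target, rtol=1e-9, atol=0):
        raise ValidationError(f"concentration {target} M not in {name} series")
    return idx


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(_asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: AnalysisConfig) -> dict[str, Any]:
    """Run every stage the provided inputs support; return the report dict.

    Numeric values in the report equal the corresponding module-level calls
    on the same inputs — orchestration adds nothing numeric.  A stage error
    aborts with the failed stage recorded under ``failed_stage``.
    """
    report: dict[str, Any] = {
        "provenance": {
            "package": f"quenchbind {__version__}",
            "config_sha256": _config_hash(config),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
    }
    stage = "load"
    try:
        series = {
            t: load_titration(p.csv, p.meta)
            for t, p in sorted(config.series_by_temp.items())
        }

        stage = "quenching"
        quench_fits = {}
        binding_fits: dict[float, BindingFit] = {}
        for t, s in series.items():
            quench_fits[t] = stern_volmer_fit(s, config.emission_nm, config.tau0_s)
            binding_fits[t] = double_log_fit(s, config.emission_nm)
        if quench_fits:
            report["quenching"] = {repr(t): _asdict(f) for t, f in quench_fits.items()}
            report["binding"] = {repr(t): _asdict(f) for t, f in binding_fits.items()}
        else:
            log.warning("no titration series provided: quenching/binding skipped")

        stage = "mechanism"
        if len(quench_fits) >= 2:
            fits = [quench_fits[t] for t in sorted(quench_fits)]
            report["mechanism"] = _asdict(
                classify_mechanism(fits, config.diffusion_limit)
            )
        else:
            log.warning("mechanism call skipped: needs >= 2 temperatures")

        stage = "thermodynamics"
        if len(binding_fits) >= 2:
            ka_by_temp = {t: f.K_a_M for t, f in binding_fits.items()}
            report["thermodynamics"] = _asdict(vant_hoff(ka_by_temp))
        else:
            log.warning("thermodynamics skipped: needs >= 2 temperatures")

        stage = "displacement"
        if config.competitor_series:
            if not binding_fits:
                log.warning("displacement skipped: no competitor-free fit")
            else:
                disp = {}
                for name, p in sorted(config.competitor_series.items()):
                    comp_series = load_titration(p.csv, p.meta)
                    fit_with = double_log_fit(comp_series, config.emission_nm)
                    t = comp_series.temperature_K
                    if t not in binding_fits:
                        raise ValidationError(
                            f"no competitor-free series at {t} K for {name}"
                        )
                    disp[name] = _asdict(
                        displacement_analysis(
                            binding_fits[t], fit_with, config.displacement_threshold
                        )
                    )
                report["displacement"] = disp

        stage = "fret"
        if config.fret is not None:
            f = config.fret
            donor = load_titration(f.donor_emission_csv, f.donor_emission_meta)
            acceptor = load_titration(
                f.acceptor_absorbance_csv,
                f.donor_emission_meta,
                kind=SpectrumKind.ABSORBANCE,
            )
            idx = _conc_index(donor.quencher_concs_M, f.quenched_conc_M, "donor")
            acc_idx = _conc_index(
                acceptor.quencher_concs_M, f.acceptor_conc_M, "acceptor"
            )
            f0 = intensity_at(donor.spectra[0], config.emission_nm)
            fq = intensity_at(donor.spectra[idx], config.emission_nm)
            report["fret"] = _asdict(
                fret_analysis(
                    donor.spectra[0],
                    acceptor.spectra[acc_idx],
                    f.acceptor_conc_M,
                    F=fq,
                    F0=f0,
                    kappa2=config.kappa2,
                    phi_D=config.phi_D,
                    eta_inv4=config.eta_inv4,
                    window_nm=config.fret_window_nm,
                )
            )
        else:
            log.info("fret skipped: no FRET inputs")

        stage = "synchronous"
        if config.synchronous_series:
            shifts = {}
            for off, p in sorted(config.synchronous_series.items()):
                sync = load_titration(p.csv, p.meta, kind=SpectrumKind.SYNCHRONOUS)
                shifts[repr(off)] = _asdict(synchronous_shift(sync, off))
            report["synchronous_shift"] = shifts
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = f"[{stage}] {exc}"
        log.error("stage %s failed: %s", stage, exc)
        raise
    return report


def write_report(report: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Write the JSON report (and a flat CSV summary of fitted constants)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=1) + "\n")
    rows = ["section,key,value"]
    for section in ("quenching", "binding", "thermodynamics"):
        block = report.get(section, {})
        flat = _flatten(block)
        rows += [f"{section},{k},{v!r}" for k, v in flat.items()]
    (out / "summary.csv").write_text("\n".join(rows) + "\n")
    return path


def _flatten(d: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, Mapping):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out
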