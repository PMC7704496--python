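"""Readers and writers for the package's plain-text formats.

Everything is tab-separated text with ``#`` comment/metadata lines:

* peak lists — one row per resonance: ``residue_index, residue_code,
  atom, shift_ppm`` plus optional ``intensity`` and ``state`` columns
  (``state`` distinguishes coexisting free/bound peaks under slow
  exchange);
* titration tables — two columns, either ``c_ligand[<unit>]/intensity``
  (fluorescence quench curve) or ``ratio/normalized_shift`` (NMR series),
  with the fixed protein concentration carried in ``# key = value``
  metadata lines;
* per-residue epitope tables and a structure-viewer attribute file;
* flat key-value fit reports and JSON run manifests.

Chemical shifts are written with 4 decimal places (sub-Hz precision at
any common field strength); writers and readers round-trip exactly at
that precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import yaml

from .csp import EpitopeMap, ResiduePerturbation
from .fitting import FitResult, FluorescenceCurve, NormalizedShiftSeries
from .units import CONCENTRATION_UNITS, format_concentration, parse_concentration

__all__ = [
    "Peak",
    "PeakList",
    "read_peak_list",
    "write_peak_list",
    "read_titration_table",
    "write_titration_table",
    "write_epitope_table",
    "write_attribute_file",
    "write_fit_report",
    "RunConfig",
    "load_config",
    "write_manifest",
]

PEAK_COLUMNS = ("residue_index", "residue_code", "atom", "shift_ppm")


class Peak(NamedTuple):
    residue_index: int
    residue_code: str
    atom: str
    shift_ppm: float
    intensity: float | None = None
    state: str = ""  # "", "free" or "bound"


@dataclass
class PeakList:
    """An indexed, duplicate-free set of assigned peaks."""

    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, str, str]] = set()
        for p in self.peaks:
            key = (p.residue_index, p.atom, p.state)
            if key in seen:
                raise ValueError(f"duplicate peak for residue {p.residue_index} atom {p.atom!r}"
                                 + (f" state {p.state!r}" if p.state else ""))
            if not np.isfinite(p.shift_ppm):
                raise ValueError(f"non-finite shift for residue {p.residue_index} atom {p.atom!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def residue_codes(self) -> dict[int, str]:
        return {p.residue_index: p.residue_code for p in self.peaks}

    def endpoint_shifts(
        self, state_preference: Sequence[str] = ("bound", "")
    ) -> dict[tuple[int, str], float]:
        """Collapse to one shift per (residue, atom).

        Where free and bound peaks coexist (slow exchange) the first state
        in ``state_preference`` wins, so the default picks the bound-state
        position at a titration endpoint.
        """
        by_state: dict[tuple[int, str], dict[str, float]] = {}
        for p in self.peaks:
            by_state.setdefault((p.residue_index, p.atom), {})[p.state] = p.shift_ppm
        out: dict[tuple[int, str], float] = {}
        for key, states in by_state.items():
            for s in state_preference:
                if s in states:
                    out[key] = states[s]
                    break
            else:  # lone peak under a non-preferred label still counts
                out[key] = next(iter(states.values()))
        return out


def _open_rows(path: Path):
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                yield lineno, None, line
            else:
                yield lineno, line.split("\t"), line


def read_peak_list(path: str | Path) -> PeakList:
    """Parse a peak-list TSV; malformed rows fail with their line number."""
    path = Path(path)
    header: list[str] | None = None
    peaks: list[Peak] = []
    for lineno, fields, _ in _open_rows(path):
        if fields is None:
            continue
        if header is None:
            header = [f.strip() for f in fields]
            missing = set(PEAK_COLUMNS) - set(header)
            if missing:
                raise ValueError(f"{path}:{lineno}: peak-list header lacks columns {sorted(missing)}")
            continue
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        row = dict(zip(header, fields))
        try:
            peak = Peak(
                residue_index=int(row["residue_index"]),
                residue_code=row["residue_code"].strip(),
                atom=row["atom"].strip(),
                shift_ppm=float(row["shift_ppm"]),
                intensity=float(row["intensity"]) if row.get("intensity", "") != "" else None,
                state=row.get("state", "").strip(),
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed peak row: {exc}") from None
        peaks.append(peak)
    if header is None:
        raise ValueError(f"{path}: missing peak-list header")
    try:
        return PeakList(peaks)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_peak_list(peaks: PeakList, path: str | Path, comment: str = "") -> None:
    """Write a peak list as TSV, shifts at 4 decimals."""
    path = Path(path)
    has_intensity = any(p.intensity is not None for p in peaks.peaks)
    has_state = any(p.state for p in peaks.peaks)
    cols = list(PEAK_COLUMNS) + (["intensity"] if has_intensity else []) + (
        ["state"] if has_state else []
    )
    with open(path, "w", newline="") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for p in sorted(peaks.peaks, key=lambda p: (p.residue_index, p.atom, p.state)):
            row = [str(p.residue_index), p.residue_code, p.atom, f"{p.shift_ppm:.4f}"]
            if has_intensity:
                row.append("" if p.intensity is None else f"{p.intensity:.6g}")
            if has_state:
                row.append(p.state)
            fh.write("\t".join(row) + "\n")


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for _, fields, line in _open_rows(path):
        if fields is not None:
            continue
        stripped = line.lstrip().lstrip("#").strip()
        if "=" in stripped:
            key, _, value = stripped.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_titration_table(path: str | Path) -> FluorescenceCurve | NormalizedShiftSeries:
    """Read a two-column titration table.

    The first header column decides the flavour: ``ratio`` gives a
    ``NormalizedShiftSeries``; ``c_ligand[<unit>]`` a ``FluorescenceCurve``
    with concentrations converted to mol/L.  Rows must be in strictly
    increasing concentration order.
    """
    path = Path(path)
    meta = _read_metadata(path)
    header: list[str] | None = None
    xs: list[float] = []
    ys: list[float] = []
    for lineno, fields, _ in _open_rows(path):
        if fields is None:
            continue
        if header is None:
            header = [f.strip() for f in fields]
            if len(header) != 2:
                raise ValueError(f"{path}:{lineno}: titration table needs exactly 2 columns")
            continue
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        try:
            xs.append(float(fields[0]))
            ys.append(float(fields[1]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
    if header is None:
        raise ValueError(f"{path}: missing titration-table header")
    x = np.asarray(xs)
    if np.any(np.diff(x) <= 0):
        raise ValueError(f"{path}: concentrations/ratios must be strictly increasing")

    if "c_protein" not in meta:
        raise ValueError(f"{path}: missing '# c_protein = <value> <unit>' metadata line")
    c_protein = parse_concentration(meta["c_protein"])

    xcol = header[0]
    if xcol == "ratio":
        return NormalizedShiftSeries(
            ratios=x,
            values=np.asarray(ys),
            c_protein=c_protein,
            residue_averaged=meta.get("residue_averaged", "true").lower() != "false",
        )
    if xcol.startswith("c_ligand[") and xcol.endswith("]"):
        unit = xcol[len("c_ligand["):-1]
        if unit not in CONCENTRATION_UNITS:
            raise ValueError(f"{path}: unknown concentration unit {unit!r} in header")
        return FluorescenceCurve(
            c_ligand=x * CONCENTRATION_UNITS[unit],
            intensity=np.asarray(ys),
            c_protein=c_protein,
            temperature_label=meta.get("temperature", ""),
        )
    raise ValueError(
        f"{path}: first column must be 'ratio' or 'c_ligand[<unit>]', got {xcol!r}"
    )


def _pick_unit(max_molar: float) -> str:
    for unit in ("M", "mM", "uM", "nM", "pM"):
        if max_molar >= CONCENTRATION_UNITS[unit]:
            return unit
    return "pM"


def write_titration_table(
    data: FluorescenceCurve | NormalizedShiftSeries, path: str | Path, comment: str = ""
) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# c_protein = {format_concentration(data.c_protein)}\n")
        if isinstance(data, FluorescenceCurve):
            if data.temperature_label:
                fh.write(f"# temperature = {data.temperature_label}\n")
            unit = _pick_unit(float(np.max(data.c_ligand))) if np.max(data.c_ligand) > 0 else "nM"
            factor = CONCENTRATION_UNITS[unit]
            fh.write(f"c_ligand[{unit}]\tintensity\n")
            for c, y in zip(data.c_ligand, data.intensity):
                fh.write(f"{c / factor:.10g}\t{y:.8g}\n")
        else:
            fh.write(f"# residue_averaged = {'true' if data.residue_averaged else 'false'}\n")
            fh.write("ratio\tnormalized_shift\n")
            for r, v in zip(data.ratios, data.values):
                fh.write(f"{r:.10g}\t{v:.8g}\n")


def write_epitope_table(
    profile: Sequence[ResiduePerturbation],
    epitope: EpitopeMap,
    path: str | Path,
    consensus: set[int] | None = None,
) -> None:
    """Per-residue TSV: perturbation, status, class, consensus membership."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# ligand = {epitope.ligand_label}\n")
        fh.write(f"# sigma0_ppm = {epitope.sigma0:.6g}\n")
        fh.write("residue_index\tresidue_code\tdelta_comb_ppm\tstatus\tclass\tin_consensus\n")
        for p in profile:
            value = epitope.delta_comb.get(p.residue_index, float("nan"))
            klass = epitope.classes[p.residue_index].value
            in_cons = "" if consensus is None else str(int(p.residue_index in consensus))
            fh.write(
                f"{p.residue_index}\t{p.residue_code}\t"
                f"{'' if np.isnan(value) else f'{value:.4f}'}\t"
                f"{p.status.value}\t{klass}\t{in_cons}\n"
            )


def write_attribute_file(epitope: EpitopeMap, path: str | Path) -> None:
    """Structure-viewer colouring attributes: ``residue_index <tab> class``."""
    with open(path, "w", newline="") as fh:
        for idx in sorted(epitope.classes):
            fh.write(f"{idx}\t{epitope.classes[idx].value}\n")


def write_fit_report(result: FitResult, path: str | Path, extra: Mapping[str, object] | None = None) -> None:
    """Flat key-value TSV report of a fit."""
    with open(path, "w", newline="") as fh:
        fh.write("key\tvalue\n")
        for name, value in result.estimates.items():
            fh.write(f"{name}\t{value:.8g}\n")
            se = result.std_errors.get(name, float("nan"))
            fh.write(f"{name}_stderr\t{se:.8g}\n")
            if name in result.bootstrap_std:
                fh.write(f"{name}_bootstrap_std\t{result.bootstrap_std[name]:.8g}\n")
        fh.write(f"residual_norm\t{result.residual_norm:.8g}\n")
        fh.write(f"converged\t{int(result.converged)}\n")
        fh.write(f"n_points\t{result.n_points}\n")
        if result.seed is not None:
            fh.write(f"seed\t{result.seed}\n")
        for key, value in (extra or {}).items():
            fh.write(f"{key}\t{value}\n")


@dataclass
class RunConfig:
    """Options for a command-line run, loadable from YAML."""

    inputs: list[Path] = field(default_factory=list)
    c_protein: float | None = None
    n_sites: float = 2.0
    kd: float | None = None
    weights: dict[str, float] | None = None
    n_starts: int = 8
    n_boot: int = 0
    seed: int = 1729
    outdir: Path = Path(".")


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    if "inputs" in raw:
        cfg.inputs = [Path(p) for p in raw["inputs"]]
        for p in cfg.inputs:
            if not p.exists():
                raise FileNotFoundError(f"{path}: input path does not exist: {p}")
    if "c_protein" in raw:
        cfg.c_protein = parse_concentration(raw["c_protein"])
    if "kd" in raw:
        cfg.kd = parse_concentration(raw["kd"])
    for key in ("n_sites", "n_starts", "n_boot", "seed"):
        if key in raw:
            setattr(cfg, key, type(getattr(cfg, key))(raw[key]))
    if "weights" in raw:
        cfg.weights = {str(k): float(v) for k, v in raw["weights"].items()}
    if "outdir" in raw:
        cfg.outdir = Path(raw["outdir"])
    return cfg


def write_manifest(
    path: str | Path,
    command: str,
    arguments: Mapping[str, object],
    seed: int | None,
    config_path: str | Path | None = None,
) -> None:
    """JSON manifest tying outputs to command, arguments, seed and versions.

    Deliberately timestamp-free so that reruns from the same config and
    seed produce byte-identical outputs.
    """
    import scipy

    from . import __version__

    manifest = {
        "command": command,
        "arguments": {k: str(v) for k, v in arguments.items()},
        "seed": seed,
        "config_sha256": (
            hashlib.sha256(Path(config_path).read_bytes()).hexdigest() if config_path else None
        ),
        "versions": {
            "csptitr": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
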