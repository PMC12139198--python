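"""File formats and run configuration.

Patient-level data travel as CSV with columns ``id,arm,qaly,cost``; solved
boundaries as a delimited text file with a JSON metadata header; run
configurations as YAML/JSON.  All floats are serialised with ``repr`` so a
write/read round trip is bit-identical.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bayes import Belief
from .boundary import Boundary, GridSpec
from .econ import EconDesign, PatientRecord
from .errors import IncompatibleFileError, SchemaError, ValueSeqError

BOUNDARY_FORMAT = "valueseq-boundary"
BOUNDARY_VERSION = 1

_REQUIRED_COLUMNS = ("id", "arm", "qaly", "cost")


@dataclass(frozen=True)
class ParseFailure:
    """A rejected input row: 1-based line number and reason."""

    line: int
    message: str


def read_patient_csv(path):
    """Read patient records from CSV (columns ``id,arm,qaly,cost``).

    Returns ``(records, failures)``.  Arm labels are normalised to upper
    case; rows with malformed or missing cells are excluded (no imputation)
    and reported in ``failures`` with their line numbers.  A missing column
    raises :class:`SchemaError`; a file yielding zero valid rows raises
    :class:`ValueSeqError`.
    """
    path = Path(path)
    records: list[PatientRecord] = []
    failures: list[ParseFailure] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header required")
        fields = [f.strip().lower() for f in reader.fieldnames]
        missing = [c for c in _REQUIRED_COLUMNS if c not in fields]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        colmap = {c: reader.fieldnames[fields.index(c)] for c in _REQUIRED_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            try:
                rec = PatientRecord(
                    id=str(row[colmap["id"]]).strip(),
                    arm=str(row[colmap["arm"]]).strip(),
                    qaly=float(row[colmap["qaly"]]),
                    cost=float(row[colmap["cost"]]),
                )
            except (TypeError, ValueError, ValueSeqError) as exc:
                failures.append(ParseFailure(line=lineno, message=str(exc)))
                continue
            records.append(rec)
    if not records:
        raise ValueSeqError(f"{path}: no valid patient rows")
    return records, failures


def write_patient_csv(path, records) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REQUIRED_COLUMNS)
        for rec in records:
            writer.writerow([rec.id, rec.arm, repr(rec.qaly), repr(rec.cost)])


def _cell(value) -> str:
    return "none" if value is None else repr(value)


def write_boundary(path, boundary: Boundary) -> None:
    """Serialise a solved boundary: JSON header lines then ``n,lower,upper``."""
    header = {
        "format": BOUNDARY_FORMAT,
        "version": BOUNDARY_VERSION,
        "prior": asdict(boundary.prior),
        "econ": asdict(boundary.econ),
        "grid": asdict(boundary.grid),
        "thresholds": boundary.thresholds,
        "value0": boundary.value0,
    }
    with Path(path).open("w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("n,lower,upper\n")
        for n in boundary.n_grid:
            fh.write(f"{int(n)},{_cell(boundary.lower[n])},{_cell(boundary.upper[n])}\n")


def read_boundary(path) -> Boundary:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise IncompatibleFileError(f"{path}: missing boundary header")
        try:
            header = json.loads(first[2:])
        except json.JSONDecodeError as exc:
            raise IncompatibleFileError(f"{path}: corrupt boundary header: {exc}") from exc
        if header.get("format") != BOUNDARY_FORMAT:
            raise IncompatibleFileError(
                f"{path}: not a {BOUNDARY_FORMAT} file (format={header.get('format')!r})"
            )
        if header.get("version") != BOUNDARY_VERSION:
            raise IncompatibleFileError(
                f"{path}: boundary format version {header.get('version')} is not "
                f"supported (expected {BOUNDARY_VERSION})"
            )
        colnames = fh.readline().strip()
        if colnames != "n,lower,upper":
            raise IncompatibleFileError(f"{path}: unexpected column header {colnames!r}")
        ns, lower, upper = [], [], []
        for line in fh:
            if not line.strip():
                continue
            n_str, lo_str, hi_str = line.strip().split(",")
            ns.append(int(n_str))
            lower.append(None if lo_str == "none" else float(lo_str))
            upper.append(None if hi_str == "none" else float(hi_str))
    return Boundary(
        n_grid=np.asarray(ns),
        lower=tuple(lower),
        upper=tuple(upper),
        value0=float(header["value0"]),
        prior=Belief(**header["prior"]),
        econ=EconDesign(**header["econ"]),
        grid=GridSpec(**header["grid"]),
        thresholds=dict(header["thresholds"]),
    )


def round_trip_boundary(path, boundary: Boundary) -> Boundary:
    """Write then re-read a boundary; the result equals the original."""
    write_boundary(path, boundary)
    return read_boundary(path)


@dataclass(frozen=True)
class RunConfig:
    """Fully-resolved run configuration: design, prior, grid and simulation."""

    econ: EconDesign
    prior: Belief
    grid: GridSpec | None = None
    n_reps: int = 5000
    seed: int = 0
    currency: str = "GBP"

    def resolved_grid(self) -> GridSpec:
        if self.grid is not None:
            return self.grid
        return GridSpec.from_prior(self.prior, self.econ)

    def to_dict(self) -> dict:
        return {
            "econ": asdict(self.econ),
            "prior": asdict(self.prior),
            "grid": asdict(self.resolved_grid()),
            "simulation": {"n_reps": self.n_reps, "seed": self.seed},
            "currency": self.currency,
        }


def _section(data: dict, name: str, cls, required: bool = True):
    if name not in data:
        if required:
            raise SchemaError(f"config missing required section {name!r}")
        return None
    section = data[name]
    if not isinstance(section, dict):
        raise SchemaError(f"config section {name!r} must be a mapping")
    try:
        return cls(**section)
    except TypeError as exc:
        raise SchemaError(f"config section {name!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML/JSON run configuration."""
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    econ = _section(data, "econ", EconDesign)
    prior_raw = data.get("prior")
    if not isinstance(prior_raw, dict):
        raise SchemaError("config missing required section 'prior'")
    try:
        prior = Belief(
            mu=float(prior_raw["mu"]),
            n_eff=float(prior_raw["n_eff"]),
            sigma=float(prior_raw["sigma"]),
        )
    except KeyError as exc:
        raise SchemaError(f"config section 'prior' missing key {exc}") from exc
    grid = _section(data, "grid", GridSpec, required=False)
    sim = data.get("simulation", {})
    if not isinstance(sim, dict):
        raise SchemaError("config section 'simulation' must be a mapping")
    return RunConfig(
        econ=econ,
        prior=prior,
        grid=grid,
        n_reps=int(sim.get("n_reps", 5000)),
        seed=int(sim.get("seed", 0)),
        currency=str(data.get("currency", "GBP")),
    )


def dump_config(config: RunConfig, path) -> None:
    """Write the fully-resolved configuration (defaults materialised)."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
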