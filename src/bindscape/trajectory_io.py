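"""Structures, trajectories, selections and the self-contained fixture format.

Unit contract for the whole package: lengths in Å, times in ns.  XTC files
(which store nm) are converted on read.  Trajectories are assumed pre-imaged:
both proteins whole and nearest-image; no periodic-boundary handling is done
anywhere downstream.

PDB, DCD and XTC I/O is delegated to MDAnalysis.  The fixture format is a
single-file container of our own (versioned header + topology table + a
little-endian float32 coordinate block) so tests and the synthetic-data
generator do not depend on third-party trajectory writers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "FormatError",
    "SelectionError",
    "Particle",
    "Topology",
    "Trajectory",
    "Selection",
    "read_structure",
    "write_structure",
    "write_models",
    "read_frames",
    "write_fixture",
    "read_fixture",
    "center_of_mass",
]

_FIXTURE_MAGIC = "BINDSCAPE-FIXTURE"
_FIXTURE_SCHEMA = 1


class FormatError(ValueError):
    """A file did not parse as the expected format."""


class SelectionError(ValueError):
    """A selection expression is malformed or resolves to nothing."""


@dataclass(frozen=True)
class Particle:
    index: int
    name: str
    residue_id: int
    residue_name: str
    chain_id: str
    domain_tag: str = ""
    flexible: bool = False


@dataclass
class Topology:
    """Ordered particle table.

    Particle indices are 0-based and contiguous; ``residue_id`` keeps the
    author (PDB) numbering for reporting.  ``(chain_id, residue_id)`` pairs
    identify residues uniquely.
    """

    particles: list[Particle]

    def __post_init__(self) -> None:
        for i, p in enumerate(self.particles):
            if p.index != i:
                raise ValueError(f"particle indices must be contiguous from 0; particle {i} has index {p.index}")

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain_id, residue_id) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for p in self.particles:
            seen.setdefault((p.chain_id, p.residue_id), None)
        return list(seen)

    def residue_members(self) -> dict[tuple[str, int], np.ndarray]:
        """Particle indices of each residue, keyed by (chain_id, residue_id)."""
        members: dict[tuple[str, int], list[int]] = {}
        for p in self.particles:
            members.setdefault((p.chain_id, p.residue_id), []).append(p.index)
        return {k: np.asarray(v, dtype=np.intp) for k, v in members.items()}

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.particles:
            seen.setdefault(p.chain_id, None)
        return list(seen)

    def select(self, expression: "str | Selection") -> np.ndarray:
        sel = expression if isinstance(expression, Selection) else Selection(expression)
        return sel.resolve(self)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_KEYWORDS = {"all", "none", "flexible", "rigid", "chain", "domain", "name", "resname", "resid"}
_OPS = {"and", "or", "not", "(", ")"}


@dataclass(frozen=True)
class Selection:
    """A small boolean selection language over the particle table.

    Primitives: ``all``, ``none``, ``flexible``, ``rigid``,
    ``chain A [B ...]``, ``domain TAG [...]``, ``name BB [...]``,
    ``resname GLY [...]``, ``resid 5 7-10 [...]`` (ranges accept ``-`` or ``:``).
    Combine with ``and``/``or``/``not`` and parentheses; ``and`` binds tighter
    than ``or``.
    """

    expression: str

    def resolve(self, topology: Topology) -> np.ndarray:
        """Sorted 0-based particle indices matching the expression."""
        tokens = self.expression.replace("(", " ( ").replace(")", " ) ").split()
        if not tokens:
            raise SelectionError("empty selection expression")
        mask, rest = _parse_or(tokens, topology)
        if rest:
            raise SelectionError(f"trailing tokens in selection: {' '.join(rest)!r}")
        return np.flatnonzero(mask)

    def __and__(self, other: "Selection") -> "Selection":
        return Selection(f"({self.expression}) and ({other.expression})")

    def __or__(self, other: "Selection") -> "Selection":
        return Selection(f"({self.expression}) or ({other.expression})")

    def __invert__(self) -> "Selection":
        return Selection(f"not ({self.expression})")


def _parse_or(tokens: list[str], top: Topology):
    mask, tokens = _parse_and(tokens, top)
    while tokens and tokens[0] == "or":
        rhs, tokens = _parse_and(tokens[1:], top)
        mask = mask | rhs
    return mask, tokens


def _parse_and(tokens: list[str], top: Topology):
    mask, tokens = _parse_not(tokens, top)
    while tokens and tokens[0] == "and":
        rhs, tokens = _parse_not(tokens[1:], top)
        mask = mask & rhs
    return mask, tokens


def _parse_not(tokens: list[str], top: Topology):
    if tokens and tokens[0] == "not":
        mask, rest = _parse_not(tokens[1:], top)
        return ~mask, rest
    return _parse_atom(tokens, top)


def _parse_atom(tokens: list[str], top: Topology):
    if not tokens:
        raise SelectionError("unexpected end of selection expression")
    head, rest = tokens[0], tokens[1:]
    n = top.n_particles
    if head == "(":
        mask, rest = _parse_or(rest, top)
        if not rest or rest[0] != ")":
            raise SelectionError("unbalanced parenthesis in selection")
        return mask, rest[1:]
    if head == "all":
        return np.ones(n, dtype=bool), rest
    if head == "none":
        return np.zeros(n, dtype=bool), rest
    if head == "flexible":
        return np.array([p.flexible for p in top.particles]), rest
    if head == "rigid":
        return np.array([not p.flexible for p in top.particles]), rest
    if head in {"chain", "domain", "name", "resname", "resid"}:
        values: list[str] = []
        while rest and rest[0] not in _OPS and rest[0] not in _KEYWORDS:
            values.append(rest[0])
            rest = rest[1:]
        if not values:
            raise SelectionError(f"selection keyword {head!r} needs at least one value")
        if head == "resid":
            mask = np.zeros(n, dtype=bool)
            for v in values:
                lo, hi = _parse_resid_range(v)
                for p in top.particles:
                    if lo <= p.residue_id <= hi:
                        mask[p.index] = True
            return mask, rest
        attr = {"chain": "chain_id", "domain": "domain_tag", "name": "name", "resname": "residue_name"}[head]
        wanted = set(values)
        return np.array([getattr(p, attr) in wanted for p in top.particles]), rest
    raise SelectionError(f"unknown selection token {head!r}")


def _parse_resid_range(token: str) -> tuple[int, int]:
    for sep in (":", "-"):
        if sep in token.lstrip("-") and not token.lstrip("-").isdigit():
            a, _, b = token.partition(sep)
            try:
                return int(a), int(b)
            except ValueError as exc:
                raise SelectionError(f"bad resid range {token!r}") from exc
    try:
        v = int(token)
    except ValueError as exc:
        raise SelectionError(f"bad resid {token!r}") from exc
    return v, v


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Frames × particles × 3 coordinates in Å, with ns-per-frame spacing."""

    topology: Topology
    coordinates: np.ndarray
    dt: float
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(f"coordinates must be (frames, particles, 3); got {self.coordinates.shape}")
        if self.coordinates.shape[1] != self.topology.n_particles:
            raise ValueError(
                f"coordinate particle count {self.coordinates.shape[1]} != topology {self.topology.n_particles}"
            )
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.coordinates.size and not np.all(np.isfinite(self.coordinates)):
            raise ValueError("trajectory coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return int(self.coordinates.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.dt

    def select(self, expression: "str | Selection") -> np.ndarray:
        return self.topology.select(expression)


def center_of_mass(traj: Trajectory, selection: "str | Selection | np.ndarray") -> np.ndarray:
    """Equal-mass centroid of the selection per frame, shape (n_frames, 3)."""
    if isinstance(selection, (str, Selection)):
        idx = traj.select(selection)
    else:
        idx = np.asarray(selection, dtype=np.intp)
    if idx.size == 0:
        raise SelectionError("center_of_mass: empty selection")
    return traj.coordinates[:, idx, :].mean(axis=1)


# ---------------------------------------------------------------------------
# PDB via MDAnalysis
# ---------------------------------------------------------------------------


def _mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _validate_pdb_lines(path: Path) -> int:
    """Pre-scan for malformed ATOM/HETATM records; return the record count."""
    n_atoms = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise FormatError(f"{path}: line {lineno}: ATOM record shorter than coordinate fields")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
            int(line[22:26])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: unparseable ATOM record: {exc}") from exc
        n_atoms += 1
    return n_atoms


def read_structure(path) -> tuple[Topology, np.ndarray]:
    """Read a PDB file into a Topology plus single-frame coordinates (Å).

    Particle order follows file order; chain IDs are preserved.  Domain tags
    are empty (assign them afterwards if needed) and all particles are marked
    rigid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _validate_pdb_lines(path) == 0:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        atoms = u.atoms
        chain_ids = _chain_ids(atoms)
        particles = [
            Particle(
                index=i,
                name=str(a.name),
                residue_id=int(a.resid),
                residue_name=str(a.resname),
                chain_id=chain_ids[i],
            )
            for i, a in enumerate(atoms)
        ]
        coords = atoms.positions.astype(float).copy()
    return Topology(particles), coords


def _chain_ids(atoms) -> list[str]:
    try:
        ids = [str(c) for c in atoms.chainIDs]
        if any(ids):
            return [c if c else "A" for c in ids]
    except AttributeError:
        pass
    return [str(a.segid).strip() or "A" for a in atoms]


def _as_universe(topology: Topology, coordinates: np.ndarray):
    mda = _mda()
    keys = topology.residue_keys()
    key_index = {k: i for i, k in enumerate(keys)}
    resindex = [key_index[(p.chain_id, p.residue_id)] for p in topology.particles]
    n_res = len(keys)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=topology.n_particles,
            n_residues=n_res,
            atom_resindex=resindex,
            residue_segindex=np.zeros(n_res, dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [p.name for p in topology.particles])
        u.add_TopologyAttr("resids", [k[1] for k in keys])
        res_names = {}
        for p in topology.particles:
            res_names.setdefault((p.chain_id, p.residue_id), p.residue_name)
        u.add_TopologyAttr("resnames", [res_names[k] for k in keys])
        u.add_TopologyAttr("chainIDs", [p.chain_id for p in topology.particles])
        u.add_TopologyAttr("elements", ["C"] * topology.n_particles)
        u.atoms.positions = np.asarray(coordinates, dtype=np.float32)
    return u


def write_structure(topology: Topology, coordinates: np.ndarray, path) -> None:
    """Write a single-frame PDB (coordinates in Å, %8.3f precision)."""
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.shape != (topology.n_particles, 3):
        raise ValueError(f"expected coordinates ({topology.n_particles}, 3), got {coordinates.shape}")
    u = _as_universe(topology, coordinates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_models(topology: Topology, frames: np.ndarray, path) -> None:
    """Write a multi-model PDB (one MODEL per frame)."""
    frames = np.asarray(frames, dtype=float)
    mda = _mda()
    u = _as_universe(topology, frames[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True, n_atoms=topology.n_particles) as w:
            for f in frames:
                u.atoms.positions = f.astype(np.float32)
                w.write(u.atoms)


def read_frames(topology: Topology, path, dt: float | None = None, replica_id: int = 0) -> Trajectory:
    """Read a DCD or XTC coordinate file against an existing topology.

    XTC nm values are converted to Å (MDAnalysis convention).  ``dt`` (ns per
    frame) overrides whatever the file header claims; files that carry no time
    information fall back to 0.001 ns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".xtc":
        frames, times = _read_xtc_strict(path, topology.n_particles)
    elif suffix == ".dcd":
        frames, times = _read_dcd(path, topology.n_particles)
    else:
        raise FormatError(f"unsupported trajectory format {suffix!r} (expected .dcd or .xtc)")
    if dt is None:
        file_dt = times[1] - times[0] if len(times) > 1 else 0.0
        dt = file_dt / 1000.0 if file_dt > 0 else 0.001  # file times are ps
    coords = np.asarray(frames) if frames else np.zeros((0, topology.n_particles, 3))
    return Trajectory(topology=topology, coordinates=coords, dt=float(dt), replica_id=replica_id)


def _read_xtc_strict(path, n_particles):
    """Read an XTC via the low-level XDR reader, which (unlike the buffered
    trajectory reader) errors out on a truncated trailing frame instead of
    silently dropping it.  nm -> Å conversion applied."""
    from MDAnalysis.lib.formats.libmdaxdr import XTCFile

    frames, times = [], []
    fh = XTCFile(str(path))
    try:
        if fh.n_atoms != n_particles:
            raise FormatError(
                f"{path}: atom count mismatch: file has {fh.n_atoms}, topology has {n_particles}"
            )
        while True:
            try:
                frame = fh.read()
            except StopIteration:
                break
            except Exception as exc:
                raise FormatError(f"{path}: truncated or corrupt XTC: {exc}") from exc
            frames.append(np.asarray(frame.x, dtype=float) * 10.0)
            times.append(float(frame.time))
    finally:
        fh.close()
    return frames, times


def _read_dcd(path, n_particles):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from MDAnalysis.coordinates.DCD import DCDReader

        try:
            reader = DCDReader(str(path))
        except Exception as exc:
            raise FormatError(f"{path}: could not open DCD: {exc}") from exc
        try:
            if reader.n_atoms != n_particles:
                raise FormatError(
                    f"{path}: atom count mismatch: file has {reader.n_atoms}, topology has {n_particles}"
                )
            frames, times = [], []
            try:
                for ts in reader:
                    frames.append(ts.positions.astype(float).copy())
                    times.append(float(ts.time))
            except Exception as exc:
                raise FormatError(f"{path}: truncated or corrupt DCD: {exc}") from exc
        finally:
            reader.close()
    return frames, times


# ---------------------------------------------------------------------------
# Fixture container
# ---------------------------------------------------------------------------


def write_fixture(traj: Trajectory, path) -> None:
    """Write the single-file fixture container.

    Layout: a magic line ``BINDSCAPE-FIXTURE <schema>``, one JSON header line
    (topology table, dt, replica_id, shape), then the raw little-endian
    float32 coordinate block.  Float32 inputs round-trip exactly.
    """
    header = {
        "schema": _FIXTURE_SCHEMA,
        "n_frames": traj.n_frames,
        "n_particles": traj.topology.n_particles,
        "dt": traj.dt,
        "replica_id": traj.replica_id,
        "particles": [
            [p.name, p.residue_id, p.residue_name, p.chain_id, p.domain_tag, p.flexible]
            for p in traj.topology.particles
        ],
    }
    with open(path, "wb") as fh:
        fh.write(f"{_FIXTURE_MAGIC} {_FIXTURE_SCHEMA}\n".encode())
        fh.write(json.dumps(header, separators=(",", ":")).encode())
        fh.write(b"\n")
        fh.write(np.ascontiguousarray(traj.coordinates, dtype="<f4").tobytes())


def read_fixture(path) -> Trajectory:
    """Read a fixture file written by :func:`write_fixture`."""
    with open(path, "rb") as fh:
        magic = fh.readline().decode(errors="replace").strip()
        parts = magic.split()
        if len(parts) != 2 or parts[0] != _FIXTURE_MAGIC:
            raise FormatError(f"{path}: not a bindscape fixture file")
        if int(parts[1]) != _FIXTURE_SCHEMA:
            raise FormatError(f"{path}: fixture schema version {parts[1]} != supported {_FIXTURE_SCHEMA}")
        header = json.loads(fh.readline().decode())
        blob = fh.read()
    n_frames, n_particles = header["n_frames"], header["n_particles"]
    expected = n_frames * n_particles * 3 * 4
    if len(blob) != expected:
        raise FormatError(f"{path}: coordinate block has {len(blob)} bytes, expected {expected}")
    coords = np.frombuffer(blob, dtype="<f4").reshape(n_frames, n_particles, 3).copy()
    particles = [
        Particle(index=i, name=n, residue_id=rid, residue_name=rn, chain_id=c, domain_tag=d, flexible=bool(fl))
        for i, (n, rid, rn, c, d, fl) in enumerate(header["particles"])
    ]
    return Trajectory(
        topology=Topology(particles),
        coordinates=coords,
        dt=float(header["dt"]),
        replica_id=int(header["replica_id"]),
    )
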