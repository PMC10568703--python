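"""Extended-XYZ-style snapshot I/O.

Plain-text snapshots: the first line is the particle count, the comment
line carries the box edge, reduced time and sweep index as key=value
pairs, and each atom line is ``<species symbol> x y z``.  Floats are
written with 17 significant digits so a write/read cycle is bit-exact.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np

from .particles import ParticleSet, SPECIES_SYMBOLS


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_xyz(path_or_buf, particles: ParticleSet, reduced_time: float = 0.0,
              sweep: int = 0, bonds: np.ndarray | None = None) -> None:
    """Write one snapshot; bonds (if given) go into a trailing block."""
    lines = [str(particles.n)]
    lines.append(
        f'L={_fmt(particles.L)} t_reduced={_fmt(reduced_time)} sweep={int(sweep)} '
        f'Properties=species:S:1:pos:R:3')
    for sym, row in zip(particles.species_symbols(), particles.positions):
        lines.append(f"{sym} {_fmt(row[0])} {_fmt(row[1])} {_fmt(row[2])}")
    if bonds is not None and len(bonds):
        lines.append(f"# bonds {len(bonds)}")
        for i, j in np.asarray(bonds):
            lines.append(f"# {int(i)} {int(j)}")
    text = "\n".join(lines) + "\n"
    if isinstance(path_or_buf, (str, Path)):
        Path(path_or_buf).write_text(text)
    else:
        path_or_buf.write(text)


def read_xyz(path_or_buf):
    """Read a snapshot written by :func:`write_xyz`.

    Returns ``(particles, meta, bonds)`` where ``meta`` holds
    ``t_reduced`` and ``sweep`` and ``bonds`` is an (E, 2) array (empty
    when the file carries none).
    """
    if isinstance(path_or_buf, (str, Path)):
        text = Path(path_or_buf).read_text()
    else:
        text = path_or_buf.read()
    lines = text.splitlines()
    n = int(lines[0].strip())
    meta = {}
    for tok in lines[1].split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    L = float(meta["L"])
    t_reduced = float(meta.get("t_reduced", 0.0))
    sweep = int(meta.get("sweep", 0))
    sym_to_code = {s: k for k, s in enumerate(SPECIES_SYMBOLS)}
    positions = np.empty((n, 3))
    species = np.empty(n, dtype=np.int8)
    for i in range(n):
        parts = lines[2 + i].split()
        species[i] = sym_to_code[parts[0]]
        positions[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
    bonds = []
    k = 2 + n
    if k < len(lines) and lines[k].startswith("# bonds"):
        n_bonds = int(lines[k].split()[2])
        for b in range(n_bonds):
            _, i, j = lines[k + 1 + b].split()
            bonds.append((int(i), int(j)))
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
    particles = ParticleSet(positions, species, L)
    return particles, {"t_reduced": t_reduced, "sweep": sweep}, bonds
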