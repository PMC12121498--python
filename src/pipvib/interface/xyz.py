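"""Plain and extended XYZ text formats.

The extended flavor stores one frame per configuration: the comment line
carries ``energy=<hartree>`` and ``unit=bohr|angstrom`` tokens, and each atom
line optionally carries three gradient components (hartree/bohr) after the
coordinates.  Coordinates are converted to bohr on read.
"""

from __future__ import annotations

import numpy as np

from ..constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

__all__ = ["read_xyz", "write_xyz", "read_extxyz", "write_extxyz",
           "XYZParseError"]


class XYZParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _parse_comment(comment: str) -> dict:
    meta = {}
    for token in comment.split():
        if "=" in token:
            key, _, val = token.partition("=")
            meta[key] = val
    return meta


def _read_frames(path):
    with open(path) as fh:
        lines = fh.readlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise XYZParseError("expected atom count", i + 1) from None
        if i + 1 + n >= len(lines) + 1:
            raise XYZParseError("truncated frame", i + 1)
        comment = lines[i + 1].rstrip("\n")
        atoms = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) not in (4, 7):
                raise XYZParseError(
                    f"expected 4 or 7 columns, got {len(parts)}", i + 3 + j)
            try:
                values = [float(x) for x in parts[1:]]
            except ValueError:
                raise XYZParseError("non-numeric coordinate", i + 3 + j) from None
            atoms.append((parts[0], values))
        frames.append((comment, atoms, i + 1))
        i += 2 + n
    return frames


def read_xyz(path, unit: str = "angstrom"):
    """Read (elements, coordinates-in-bohr) from the first frame of an XYZ file.

    Plain XYZ is conventionally in angstrom; pass ``unit='bohr'`` (or put
    ``unit=bohr`` in the comment line) to override.
    """
    frames = _read_frames(path)
    if not frames:
        raise XYZParseError("empty file", 1)
    comment, atoms, _ = frames[0]
    meta = _parse_comment(comment)
    unit = meta.get("unit", unit).lower()
    scale = 1.0 if unit == "bohr" else ANGSTROM_TO_BOHR
    elements = tuple(a[0] for a in atoms)
    coords = np.array([a[1][:3] for a in atoms]) * scale
    return elements, coords


def write_xyz(path, elements, coordinates, unit: str = "angstrom",
              comment: str = "") -> None:
    """Write a single frame; coordinates given in bohr, stored in ``unit``."""
    coords = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    scale = 1.0 if unit == "bohr" else BOHR_TO_ANGSTROM
    with open(path, "w") as fh:
        fh.write(f"{len(coords)}\n")
        fh.write(f"unit={unit} {comment}".rstrip() + "\n")
        for el, xyz in zip(elements, coords * scale):
            fh.write(f"{el:4s} {xyz[0]:22.14e} {xyz[1]:22.14e} {xyz[2]:22.14e}\n")


def write_extxyz(path, training_set, unit: str = "bohr") -> None:
    """Write a training set (geometries + energies + gradients) as extended XYZ."""
    scale = 1.0 if unit == "bohr" else BOHR_TO_ANGSTROM
    geoms = training_set.geometries
    elements = training_set.elements or tuple(
        "X" for _ in range(geoms.shape[1]))
    with open(path, "w") as fh:
        for geom, energy, grad in zip(geoms, training_set.energies,
                                      training_set.gradients):
            fh.write(f"{geom.shape[0]}\n")
            fh.write(f"energy={energy:.16e} unit={unit} gradients=true\n")
            for el, xyz, g in zip(elements, geom * scale, grad):
                fh.write(f"{el:4s} "
                         f"{xyz[0]:22.14e} {xyz[1]:22.14e} {xyz[2]:22.14e} "
                         f"{g[0]:22.14e} {g[1]:22.14e} {g[2]:22.14e}\n")


def read_extxyz(path):
    """Read an extended-XYZ training set written by :func:`write_extxyz`."""
    from ..model_systems import SyntheticTrainingSet

    frames = _read_frames(path)
    if not frames:
        raise XYZParseError("empty file", 1)
    geoms, energies, grads = [], [], []
    elements = None
    for comment, atoms, line in frames:
        meta = _parse_comment(comment)
        if "energy" not in meta:
            raise XYZParseError("missing energy= token in comment", line)
        unit = meta.get("unit", "bohr").lower()
        scale = 1.0 if unit == "bohr" else ANGSTROM_TO_BOHR
        if any(len(vals) != 6 for _, vals in atoms):
            raise XYZParseError("missing gradient columns", line)
        elements = tuple(el for el, _ in atoms)
        arr = np.array([vals for _, vals in atoms])
        geoms.append(arr[:, :3] * scale)
        grads.append(arr[:, 3:])
        energies.append(float(meta["energy"]))
    return SyntheticTrainingSet(
        geometries=np.array(geoms), energies=np.array(energies),
        gradients=np.array(grads), elements=elements)
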