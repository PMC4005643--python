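"""Nearest-neighbor thermodynamic model for intermolecular RNA duplexes.

The model scores a duplex as

    dG = duplex_init
       + sum of stacking terms over consecutive base pairs
       + loop initiation (+ asymmetry) terms for bulges / internal loops
       + a terminal penalty for each helix end closed by A:U or G:U

at a fixed temperature of 37 C.  Pairable bases are the Watson-Crick pairs
plus G:U wobbles; dangling ends and terminal-mismatch bonuses are not
modelled.  The default parameter file ships Turner-style stacks with
``duplex_init`` and ``terminal_au`` set to zero, so energies are
hybridization free energies on the scale reported by RNAhybrid-like tools
(a perfectly complementary helix scores the bare stacking sum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

#: fixed base encoding used by the dynamic program
BASES = "ACGU"
BASE_CODE = {b: i for i, b in enumerate(BASES)}

#: legal intermolecular pairs (Watson-Crick + wobble)
PAIRABLE = frozenset(
    {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
)

#: 1.75 * R * T at 37 C, the Jacobson-Stockmayer prefactor for loop
#: extrapolation, kcal/mol
_LOOP_EXTRAPOLATION = 1.75 * 0.0019872 * 310.15

INF = float("inf")


def encode(residues: str) -> np.ndarray:
    """Encode an RNA string as uint8 codes (A=0, C=1, G=2, U=3)."""
    return np.array([BASE_CODE[c] for c in residues], dtype=np.uint8)


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIRABLE


def is_wobble(a: str, b: str) -> bool:
    return (a, b) in (("G", "U"), ("U", "G"))


@dataclass
class EnergyModel:
    """Parameter tables for the duplex dynamic program.

    Attributes
    ----------
    stack:
        4x4x4x4 array ``stack[x1, x2, y1, y2]`` holding the free energy of
        the stack 5'-x1 x2-3' / 3'-y1 y2-5' (x1:y1 and x2:y2 are pairs);
        +inf where either doublet position is not a legal pair.
    bulge_init, internal_init:
        loop initiation penalties indexed by loop size (index 0 unused),
        tabulated out to ``max_bulge`` / ``max_internal`` with logarithmic
        extrapolation beyond the parameter file's range.
    """

    stack: np.ndarray
    pair_ok: np.ndarray
    bulge_init: np.ndarray
    internal_init: np.ndarray
    asymmetry: float
    asymmetry_max: float
    terminal_au_penalty: float
    duplex_init: float
    max_bulge: int
    max_internal: int
    source: str = field(default="builtin")

    # -- scalar accessors used by scoring code and the test oracle --------

    def stack_energy(self, x1: str, x2: str, y1: str, y2: str) -> float:
        """Energy of the stack 5'-x1 x2-3' / 3'-y1 y2-5' (kcal/mol)."""
        return float(
            self.stack[BASE_CODE[x1], BASE_CODE[x2], BASE_CODE[y1], BASE_CODE[y2]]
        )

    def loop_init(self, kind: str, size: int) -> float:
        if size < 1:
            raise ValueError("loop size must be >= 1")
        if kind == "bulge":
            if size > self.max_bulge:
                raise ValueError(f"bulge size {size} exceeds max_bulge")
            return float(self.bulge_init[size])
        if kind == "internal":
            if size > self.max_internal:
                raise ValueError(f"internal loop size {size} exceeds max_internal")
            return float(self.internal_init[size])
        raise ValueError(f"unknown loop kind {kind!r}")

    def asymmetry_penalty(self, n1: int, n2: int) -> float:
        return min(self.asymmetry_max, self.asymmetry * abs(n1 - n2))

    def terminal_penalty(self, a: str, b: str) -> float:
        """Penalty for a helix end closed by the pair a:b."""
        if not can_pair(a, b):
            raise ValueError(f"{a}:{b} is not a legal pair")
        return self.terminal_au_penalty if (a, b) != ("C", "G") and (a, b) != ("G", "C") else 0.0


def _extrapolate(table: dict[int, float], upto: int) -> np.ndarray:
    """Fill loop penalties to ``upto`` with Jacobson-Stockmayer log growth."""
    out = np.full(upto + 1, INF)
    nmax = max(table)
    for size, val in table.items():
        if size <= upto:
            out[size] = val
    for size in range(nmax + 1, upto + 1):
        out[size] = table[nmax] + _LOOP_EXTRAPOLATION * math.log(size / nmax)
    return out


def load_model(path: str | Path) -> EnergyModel:
    """Load an EnergyModel from a plain-text parameter table."""
    stack = np.full((4, 4, 4, 4), INF)
    bulge: dict[int, float] = {}
    internal: dict[int, float] = {}
    params: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0] == "stack":
                top, bottom, dg = fields[1], fields[2], float(fields[3])
                _set_stack(stack, top, bottom, dg)
            elif fields[0] == "loop":
                kind, size, dg = fields[1], int(fields[2]), float(fields[3])
                (bulge if kind == "bulge" else internal)[size] = dg
            elif fields[0] == "param":
                params[fields[1]] = float(fields[2])
            else:
                raise ValueError(f"unrecognized parameter line: {line!r}")
    max_bulge = int(params.get("max_bulge", 15))
    max_internal = int(params.get("max_internal", 30))
    pair_ok = np.zeros((4, 4), dtype=np.uint8)
    for a, b in PAIRABLE:
        pair_ok[BASE_CODE[a], BASE_CODE[b]] = 1
    model = EnergyModel(
        stack=stack,
        pair_ok=pair_ok,
        bulge_init=_extrapolate(bulge, max_bulge),
        internal_init=_extrapolate(internal, max_internal),
        asymmetry=params.get("asymmetry", 0.6),
        asymmetry_max=params.get("asymmetry_max", 3.0),
        terminal_au_penalty=params.get("terminal_au", 0.0),
        duplex_init=params.get("duplex_init", 0.0),
        max_bulge=max_bulge,
        max_internal=max_internal,
        source=str(path),
    )
    _check_complete(model)
    return model


def _set_stack(stack: np.ndarray, top: str, bottom: str, dg: float) -> None:
    """Install a stack value and its strand-exchange mirror.

    ``top`` is read 5'->3', ``bottom`` 3'->5'; reading the duplex from the
    other strand maps 5'-x1 x2 / 3'-y1 y2 onto 5'-y2 y1 / 3'-x2 x1, which
    must score identically.
    """
    (x1, x2), (y1, y2) = top, bottom
    for (a1, a2, b1, b2) in [(x1, x2, y1, y2), (y2, y1, x2, x1)]:
        if not (can_pair(a1, b1) and can_pair(a2, b2)):
            raise ValueError(f"stack {top}/{bottom} contains an illegal pair")
        stack[BASE_CODE[a1], BASE_CODE[a2], BASE_CODE[b1], BASE_CODE[b2]] = dg


def _check_complete(model: EnergyModel) -> None:
    """Every doublet of legal pairs must have a finite stacking energy."""
    for a1, b1 in PAIRABLE:
        for a2, b2 in PAIRABLE:
            e = model.stack_energy(a1, a2, b1, b2)
            if not math.isfinite(e):
                raise ValueError(f"missing stack 5'{a1}{a2}/3'{b1}{b2}")


def default_model() -> EnergyModel:
    """The packaged Turner-style nearest-neighbor table at 37 C."""
    ref = resources.files("bulgescan.data").joinpath("nn_params_37.tsv")
    with resources.as_file(ref) as path:
        model = load_model(path)
    model.source = "builtin"
    return model
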