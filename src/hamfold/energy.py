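"""Nearest-neighbor thermodynamic model.

The model supplies every Boltzmann factor the dynamic programs need:

* ``hairpin_energy(seq, i, j)`` — hairpin loop closed by (i, j);
* ``interior_energy(seq, i, j, h, l)`` — stack, bulge or internal loop between
  closing pair (i, j) and inner pair (h, l);
* affine multiloop ``a + b * branches + c * unpaired``;
* exterior (unconstrained) unpaired bases cost 0, so the open chain has
  energy 0 and Boltzmann factor 1.

``structure_energy`` evaluates a whole structure by the same loop
decomposition, which makes the enumeration oracle and the recursions agree by
construction. Free energies are in kcal/mol; temperatures in kelvin.

Temperatures other than 37 C are handled by splitting dG37 into enthalpy and
entropy with an assumed dH/dG37 ratio for stacks (loop initiations are taken
as purely entropic): dG(T) = dG37 * T/T37 + dH * (1 - T/T37). This is an
approximation, made explicit in the parameter file, not a fitted melting
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .structures import InputError, RnaSequence, SecondaryStructure

GAS_CONSTANT = 1.9872e-3  # kcal / (mol K)
T37 = 310.15
PAIR_ORDER = ("AU", "CG", "GC", "UA", "GU", "UG")
_PAIR_CODE = {p: k for k, p in enumerate(PAIR_ORDER)}


def boltzmann(e: float, T: float) -> float:
    """exp(-e / (R T)) for e in kcal/mol, T in kelvin."""
    if T <= 0:
        raise InputError(f"temperature must be positive, got {T}")
    return math.exp(-e / (GAS_CONSTANT * T))


def pair_code(a: str, b: str) -> int:
    """0..5 in PAIR_ORDER for an allowed pair, -1 otherwise."""
    return _PAIR_CODE.get(a + b, -1)


@dataclass
class EnergyModel:
    """Loop free energies at a fixed temperature.

    All dG tables are already rescaled to ``temperature``; reloading at a new
    temperature produces a new instance (see :meth:`turner2004` / :meth:`toy`).
    """

    name: str
    version: str
    temperature: float
    stack: np.ndarray                 # (6, 6) dG, pair-on-pair
    hairpin_init: dict[int, float]    # by loop size (unpaired bases)
    bulge_init: dict[int, float]
    interior_init: dict[int, float]
    asym_per_nt: float
    asym_max: float
    ml_a: float
    ml_b: float
    ml_c: float
    terminal_penalty: float           # per non-GC/CG closing pair
    R: float = GAS_CONSTANT
    _extrap: float = field(init=False)

    def __post_init__(self) -> None:
        # 1.75 R T ln(n/nmax) loop-size extrapolation coefficient
        self._extrap = 1.75 * self.R * self.temperature

    # -- loop energies -----------------------------------------------------

    def _init_energy(self, table: dict[int, float], n: int) -> float:
        if n in table:
            return table[n]
        nmax = max(table)
        if n < min(table):
            return table[min(table)]
        return table[nmax] + self._extrap * math.log(n / nmax)

    def _terminal(self, code: int) -> float:
        # codes 1, 2 are CG / GC
        return 0.0 if code in (1, 2) else self.terminal_penalty

    def hairpin_energy(self, seq: RnaSequence, i: int, j: int) -> float:
        code = pair_code(seq[i], seq[j])
        if code < 0:
            raise InputError(f"pair ({i},{j}) = {seq[i]}{seq[j]} not allowed")
        return self._init_energy(self.hairpin_init, j - i - 1) + self._terminal(code)

    def interior_energy(self, seq: RnaSequence, i: int, j: int,
                        h: int, l: int) -> float:
        """Two-loop (stack / bulge / internal) energy; requires i < h < l < j."""
        if not i < h < l < j:
            raise InputError(f"need i < h < l < j, got ({i},{h},{l},{j})")
        c1 = pair_code(seq[i], seq[j])
        c2 = pair_code(seq[h], seq[l])
        if c1 < 0 or c2 < 0:
            raise InputError(f"disallowed pair in two-loop ({i},{j})/({h},{l})")
        n1, n2 = h - i - 1, j - l - 1
        if n1 == 0 and n2 == 0:
            return float(self.stack[c1, c2])
        pen = self._terminal(c1) + self._terminal(c2)
        if n1 == 0 or n2 == 0:
            return self._init_energy(self.bulge_init, n1 + n2) + pen
        asym = min(self.asym_per_nt * abs(n1 - n2), self.asym_max)
        return self._init_energy(self.interior_init, n1 + n2) + asym + pen

    def multiloop_energy(self, branches: int, unpaired: int) -> float:
        """Closing penalty a + b per inner branch + c per unpaired base. The
        closing pair itself is charged via ``a``; ``branches`` counts the inner
        helices only."""
        return self.ml_a + self.ml_b * branches + self.ml_c * unpaired

    def boltzmann(self, e: float) -> float:
        return boltzmann(e, self.temperature)

    # -- whole-structure energy --------------------------------------------

    def structure_energy(self, seq: RnaSequence, s: SecondaryStructure) -> float:
        """Total loop-decomposition free energy; open chain -> 0."""
        if s.L != seq.L:
            raise InputError(f"structure length {s.L} != sequence length {seq.L}")
        total = 0.0
        for (i, j), children in _loops(s):
            if pair_code(seq[i], seq[j]) < 0:
                raise InputError(
                    f"pair ({i},{j}) = {seq[i]}{seq[j]} disallowed by model {self.name}")
            if not children:
                total += self.hairpin_energy(seq, i, j)
            elif len(children) == 1:
                h, l = children[0]
                total += self.interior_energy(seq, i, j, h, l)
            else:
                unpaired = (j - i - 1) - sum(l - h + 1 for h, l in children)
                total += self.multiloop_energy(len(children), unpaired)
                total += self.ml_b  # the closing pair's own branch term
        return total

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_file(cls, path_or_text, temperature: float = T37) -> "EnergyModel":
        raw = _read_param_text(path_or_text)
        return _build_model(raw, temperature)

    @classmethod
    def turner2004(cls, temperature: float = T37) -> "EnergyModel":
        text = (resources.files("hamfold.data") / "turner2004_min.txt").read_text()
        return cls.from_file(text, temperature)

    @classmethod
    def toy(cls, temperature: float = T37) -> "EnergyModel":
        """Human-checkable model: -1 kcal/mol per stacked pair, all loops 0."""
        return cls(
            name="toy", version="1.0", temperature=temperature,
            stack=np.full((6, 6), -1.0),
            hairpin_init={3: 0.0}, bulge_init={1: 0.0}, interior_init={2: 0.0},
            asym_per_nt=0.0, asym_max=0.0,
            ml_a=0.0, ml_b=0.0, ml_c=0.0, terminal_penalty=0.0,
        )


def get_model(name: str, temperature: float = T37) -> EnergyModel:
    if name in ("turner2004", "turner2004-min", "default"):
        return EnergyModel.turner2004(temperature)
    if name == "toy":
        return EnergyModel.toy(temperature)
    return EnergyModel.from_file(name, temperature)


def _loops(s: SecondaryStructure):
    """Yield (pair, direct children pairs) for every pair of the structure."""
    ordered = sorted(s.pairs)
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in ordered}
    stack: list[tuple[int, int]] = []
    for p in ordered:
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        if stack and stack[-1][0] < p[0] and p[1] < stack[-1][1]:
            children[stack[-1]].append(p)
        stack.append(p)
    return [(p, children[p]) for p in ordered]


# ---------------------------------------------------------------------------
# Parameter-file parsing
# ---------------------------------------------------------------------------

def _read_param_text(path_or_text) -> dict:
    import os

    text = str(path_or_text)
    if "\n" not in text and os.path.exists(text):
        with open(text) as fh:
            text = fh.read()
    meta: dict = {"name": "unnamed", "version": "0"}
    section = None
    rows: dict[str, list[list[str]]] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            rows[section] = []
        elif section is None:
            key, _, val = line.partition(" ")
            meta[key] = val.strip()
        else:
            rows[section].append(line.split())
    meta["rows"] = rows
    return meta


def _build_model(raw: dict, temperature: float) -> EnergyModel:
    rows = raw["rows"]
    try:
        pairs = tuple(rows["pairs"][0])
        if pairs != PAIR_ORDER:
            raise InputError(f"parameter file pair order {pairs} != {PAIR_ORDER}")
        stack37 = np.array([[float(v) for v in r] for r in rows["stack"]])
        if stack37.shape != (6, 6):
            raise InputError("stack table must be 6x6")
        hairpin = {int(n): float(g) for n, g in rows["hairpin"]}
        bulge = {int(n): float(g) for n, g in rows["bulge"]}
        interior = {int(n): float(g) for n, g in rows["interior"]}
        asym_per_nt, asym_max = (float(v) for v in rows["asymmetry"][0])
        ml_a, ml_b, ml_c = (float(v) for v in rows["multiloop"][0])
        terminal = float(rows["terminal"][0][0])
        ratio = float(rows["enthalpy_ratio"][0][0])
    except (KeyError, IndexError, ValueError) as exc:
        raise InputError(f"malformed parameter table: {exc}") from exc

    tfac = temperature / T37
    # stacks: dH = ratio * dG37; loop initiations: purely entropic (dH = 0)
    stack = stack37 * tfac + ratio * stack37 * (1.0 - tfac)
    scale_loop = lambda tab: {n: g * tfac for n, g in tab.items()}
    return EnergyModel(
        name=raw.get("name", "unnamed"), version=raw.get("version", "0"),
        temperature=temperature, stack=stack,
        hairpin_init=scale_loop(hairpin), bulge_init=scale_loop(bulge),
        interior_init=scale_loop(interior),
        asym_per_nt=asym_per_nt * tfac, asym_max=asym_max * tfac,
        ml_a=ml_a * tfac, ml_b=ml_b * tfac, ml_c=ml_c * tfac,
        terminal_penalty=terminal * tfac,
    )
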