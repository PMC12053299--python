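"""Boltzmann weighting, conformer grouping, pruning and normalization.

Conformer-ensemble tools report raw populations alongside relative energies;
those raw populations may include degeneracy contributions and are therefore
consumed as given rather than recomputed.  :func:`boltzmann` is provided for
synthetic work.  The bookkeeping pipeline is: prune high-energy/low-weight
conformers, combine conformers whose differences are invisible to the RDC
analysis into groups, and renormalize the retained group populations to 1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "KB_KCAL",
    "PopulationTable",
    "boltzmann",
    "prune_conformers",
    "combine_and_normalize",
    "read_population_table",
    "write_population_table",
]

#: Boltzmann constant, kcal/(mol K).
KB_KCAL = 0.0019872041


@dataclass(frozen=True)
class PopulationTable:
    """Per-conformer energies/populations plus group-level combined numbers.

    ``groups`` maps conformer id -> group id; ``p_comb`` and ``p_norm`` are
    per-group and populated by :func:`combine_and_normalize`.
    """

    conf_ids: tuple[str, ...]
    e_rel: tuple[float, ...]
    p_raw: tuple[float, ...]
    groups: dict = field(default_factory=dict)
    p_comb: dict = field(default_factory=dict)
    p_norm: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "conf_ids", tuple(self.conf_ids))
        object.__setattr__(self, "e_rel", tuple(float(e) for e in self.e_rel))
        object.__setattr__(self, "p_raw", tuple(float(p) for p in self.p_raw))
        n = len(self.conf_ids)
        if not (len(self.e_rel) == len(self.p_raw) == n):
            raise ValueError("conf_ids, e_rel and p_raw must have equal lengths")
        if any(p < 0 for p in self.p_raw):
            raise ValueError("raw populations must be non-negative")

    def __len__(self) -> int:
        return len(self.conf_ids)


def boltzmann(e_rel, temperature: float = 298.15) -> np.ndarray:
    """Boltzmann populations from relative energies (kcal/mol) at T (K).

    p_i = exp(-e_i / kT) / sum_j exp(-e_j / kT), evaluated with the
    max-shift trick for numerical stability.
    """
    e = np.asarray(e_rel, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy vector")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x = -(e - e.min()) / (KB_KCAL * temperature)
    w = np.exp(x)
    return w / w.sum()


def prune_conformers(
    tbl: PopulationTable, e_max: float = 2.2, p_min: float = 0.01
) -> PopulationTable:
    """Drop conformers with e_rel > e_max AND p_raw < p_min (conjunctive rule).

    A high-energy conformer with substantial raw population is retained, as
    is a low-population conformer within the energy window.
    """
    keep = [
        i
        for i in range(len(tbl))
        if not (tbl.e_rel[i] > e_max and tbl.p_raw[i] < p_min)
    ]
    if not keep:
        raise ValueError("pruning removed every conformer")
    ids = tuple(tbl.conf_ids[i] for i in keep)
    return replace(
        tbl,
        conf_ids=ids,
        e_rel=tuple(tbl.e_rel[i] for i in keep),
        p_raw=tuple(tbl.p_raw[i] for i in keep),
        groups={c: g for c, g in tbl.groups.items() if c in ids},
        p_comb={},
        p_norm={},
    )


def combine_and_normalize(tbl: PopulationTable) -> PopulationTable:
    """Sum raw populations within each group, then normalize over retained groups.

    p_comb(g) = sum of p_raw over members of g;
    p_norm(g) = p_comb(g) / sum over retained groups.
    Every conformer in the table must carry a group assignment.
    """
    unassigned = [c for c in tbl.conf_ids if c not in tbl.groups]
    if unassigned:
        raise ValueError(f"conformers without a group assignment: {unassigned}")
    p_comb: dict = {}
    for cid, p in zip(tbl.conf_ids, tbl.p_raw):
        g = tbl.groups[cid]
        p_comb[g] = p_comb.get(g, 0.0) + p
    total = sum(p_comb.values())
    if total <= 0:
        raise ValueError("total retained population is zero")
    p_norm = {g: p / total for g, p in p_comb.items()}
    return replace(tbl, p_comb=p_comb, p_norm=p_norm)


# ---------------------------------------------------------------------------
# I/O — same delimited dialect as the RDC tables (header, '#' comments, NA)


def read_population_table(path_or_buf) -> PopulationTable:
    """Read a ``conf e_rel p_raw [group]`` table."""
    from .molio import TableParseError

    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    rows = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            rows.append((lineno, line.split()))
    if not rows:
        raise TableParseError("no header row found")
    _, header = rows[0]
    for col in ("conf", "e_rel", "p_raw"):
        if col not in header:
            raise TableParseError(f"missing mandatory column {col!r}")
    ids, e_rel, p_raw, groups = [], [], [], {}
    for lineno, parts in rows[1:]:
        if len(parts) != len(header):
            raise TableParseError(f"line {lineno}: expected {len(header)} fields")
        cell = dict(zip(header, parts))
        ids.append(cell["conf"])
        try:
            e_rel.append(float(cell["e_rel"]))
            p_raw.append(float(cell["p_raw"]))
        except ValueError as exc:
            raise TableParseError(f"line {lineno}: non-numeric cell") from exc
        g = cell.get("group", "NA")
        if g != "NA":
            groups[cell["conf"]] = g
    return PopulationTable(conf_ids=tuple(ids), e_rel=tuple(e_rel), p_raw=tuple(p_raw), groups=groups)


def write_population_table(tbl: PopulationTable, path) -> None:
    out = io.StringIO()
    out.write("conf\te_rel\tp_raw\tgroup\n")
    for cid, e, p in zip(tbl.conf_ids, tbl.e_rel, tbl.p_raw):
        g = tbl.groups.get(cid, "NA")
        out.write(f"{cid}\t{e:.3f}\t{p:.4f}\t{g}\n")
    with open(path, "w") as fh:
        fh.write(out.getvalue())
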