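"""Reading, filtering and writing of protein structure files.

Structures (PDB or mmCIF, parsed with gemmi) are reduced to per-chain
C-alpha traces plus the header metadata the downstream analysis filters
on: resolution, experimental method, keyword text and the HELIX/SHEET
(or struct_conf / struct_sheet_range) secondary-structure ranges.

Database selection follows the usual quality gates for geometry surveys:
resolution explicitly defined and <= 2.0 A, NMR entries excluded.  Bonds
are annotated as *cis* (C-alpha distance <= 3.4 A; only C-alpha atoms are
kept, so the short virtual bond is the cis signature) or as chain *breaks*
(outside 2.7-4.3 A); scans never cross a flagged bond.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "StructureParseError",
    "EmptyRecordError",
    "CAlphaChain",
    "StructureRecord",
    "read_structure",
    "select_structures",
    "annotate_bonds",
    "filter_keyword",
    "sample_random_subset",
    "write_fixture",
    "write_entry_list",
]

CIS_MAX = 3.4
BREAK_MIN = 2.7
BREAK_MAX = 4.3


class StructureParseError(ValueError):
    """The file could not be parsed as a structure."""


class EmptyRecordError(ValueError):
    """The file parsed but contains no C-alpha atoms."""


@dataclass
class CAlphaChain:
    """One polypeptide chain reduced to its C-alpha trace.

    Per-residue arrays all have length nres; the per-bond cis/break flags
    have length nres - 1 (bond i joins residues i and i+1, 0-based here).
    Residue numbers are strictly increasing (residues that would break the
    ordering, e.g. insertion-code duplicates, are dropped on reading).
    """

    chain_id: str
    residue_numbers: np.ndarray
    residue_names: list[str]
    coords: np.ndarray
    helix_flag: np.ndarray = None
    sheet_flag: np.ndarray = None
    cis_flag: np.ndarray = None
    break_flag: np.ndarray = None

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, int)
        self.coords = np.asarray(self.coords, float)
        n = len(self.residue_numbers)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (nres, 3)")
        if len(self.residue_names) != n:
            raise ValueError("residue_names length mismatch")
        if n > 1 and np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue numbers must be strictly increasing")
        for attr, m in (("helix_flag", n), ("sheet_flag", n),
                        ("cis_flag", max(n - 1, 0)), ("break_flag", max(n - 1, 0))):
            v = getattr(self, attr)
            v = np.zeros(m, bool) if v is None else np.asarray(v, bool)
            if len(v) != m:
                raise ValueError(f"{attr} must have length {m}")
            setattr(self, attr, v)

    @property
    def nres(self) -> int:
        return len(self.residue_numbers)

    def flagged_bonds(self) -> np.ndarray:
        """Bonds a segment window must not cross (cis or break)."""
        return self.cis_flag | self.break_flag


@dataclass
class StructureRecord:
    """One structure entry: header metadata plus its C-alpha chains."""

    entry_id: str
    resolution: float | None
    method: str                       # 'xray' | 'nmr' | 'em' | 'other'
    keywords: str
    helix_ranges: list = field(default_factory=list)   # (chain, first, last)
    sheet_ranges: list = field(default_factory=list)
    chains: list = field(default_factory=list)

    def __post_init__(self):
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")


def _classify_method(text: str) -> str:
    t = text.upper()
    if "NMR" in t:
        return "nmr"
    if "X-RAY" in t or "DIFFRACTION" in t or "NEUTRON" in t:
        return "xray"
    if "MICROSCOPY" in t or "CRYO" in t or t.startswith("EM"):
        return "em"
    return "other"


def _best_ca(residue) -> gemmi.Atom | None:
    """Highest-occupancy C-alpha of a residue (first wins on ties)."""
    best = None
    for atom in residue:
        if atom.name == "CA" and atom.element.name == "C":
            if best is None or atom.occ > best.occ:
                best = atom
    return best


def read_structure(path, fmt: str = "auto") -> StructureRecord:
    """Parse a PDB or mmCIF file into a StructureRecord.

    Residues lacking a C-alpha atom are dropped; alternate locations
    resolve to the highest-occupancy copy (first on a tie).  Helix/sheet
    flags come from the file's own annotation records; no recomputation.
    Raises StructureParseError on unreadable input and EmptyRecordError
    when no C-alpha atom survives.
    """
    path = str(path)
    try:
        if fmt == "auto":
            st = gemmi.read_structure(path)
        else:
            cf = gemmi.CoorFormat.Pdb if fmt == "pdb" else gemmi.CoorFormat.Mmcif
            st = gemmi.read_structure(path, format=cf)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc

    info = dict(st.info)
    keywords = info.get("_struct_keywords.text", "") or info.get(
        "_struct_keywords.pdbx_keywords", ""
    )
    method = _classify_method(info.get("_exptl.method", ""))
    resolution = float(st.resolution) if st.resolution > 0 else None

    helix_ranges = [
        (h.start.chain_name, h.start.res_id.seqid.num, h.end.res_id.seqid.num)
        for h in st.helices
    ]
    sheet_ranges = [
        (s.start.chain_name, s.start.res_id.seqid.num, s.end.res_id.seqid.num)
        for sheet in st.sheets
        for s in sheet.strands
    ]

    chains = []
    if len(st) > 0:
        for ch in st[0]:
            nums, names, xyz = [], [], []
            for res in ch:
                atom = _best_ca(res)
                if atom is None:
                    continue
                if nums and res.seqid.num <= nums[-1]:
                    continue            # insertion-code duplicate; keep first
                nums.append(res.seqid.num)
                names.append(res.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if not nums:
                continue
            nums = np.array(nums)
            helix = np.zeros(len(nums), bool)
            sheet = np.zeros(len(nums), bool)
            for cid, lo, hi in helix_ranges:
                if cid == ch.name:
                    helix |= (nums >= lo) & (nums <= hi)
            for cid, lo, hi in sheet_ranges:
                if cid == ch.name:
                    sheet |= (nums >= lo) & (nums <= hi)
            chains.append(
                CAlphaChain(ch.name, nums, names, np.array(xyz),
                            helix_flag=helix, sheet_flag=sheet)
            )
    if not chains:
        raise EmptyRecordError(f"{path}: no C-alpha atoms found")

    return StructureRecord(
        entry_id=info.get("_entry.id") or st.name or Path(path).stem,
        resolution=resolution,
        method=method,
        keywords=keywords,
        helix_ranges=helix_ranges,
        sheet_ranges=sheet_ranges,
        chains=chains,
    )


def select_structures(records, max_resolution: float = 2.0,
                      exclude_nmr: bool = True) -> list:
    """Keep records with a defined resolution <= max_resolution and, when
    exclude_nmr is set, a non-NMR method.  Order preserved; boundary
    inclusive ("2.0 A or better")."""
    if max_resolution <= 0:
        raise ValueError("max_resolution must be positive")
    out = []
    for rec in records:
        if rec.resolution is None or rec.resolution > max_resolution:
            continue
        if exclude_nmr and rec.method == "nmr":
            continue
        out.append(rec)
    return out


def annotate_bonds(chain: CAlphaChain, cis_max: float = CIS_MAX,
                   break_min: float = BREAK_MIN,
                   break_max: float = BREAK_MAX) -> CAlphaChain:
    """Return a copy of the chain with cis/break bond flags set from the
    virtual-bond lengths: length <= cis_max flags cis; length outside
    [break_min, break_max] flags a chain break."""
    if chain.nres < 2:
        raise ValueError("need at least 2 residues to annotate bonds")
    d = np.linalg.norm(np.diff(chain.coords, axis=0), axis=1)
    return dataclasses.replace(
        chain,
        cis_flag=d <= cis_max,
        break_flag=(d < break_min) | (d > break_max),
    )


def filter_keyword(records, token: str) -> list:
    """Keep records whose keyword text contains the token (case-insensitive
    substring match, e.g. 'ALLO' for allostery-related entries)."""
    if not token:
        raise ValueError("token must be non-empty")
    t = token.upper()
    return [r for r in records if t in r.keywords.upper()]


def sample_random_subset(records, size: int, seed: int) -> list:
    """Uniform sample of `size` records without replacement, reproducible
    for a given seed; input order preserved within the sample."""
    if size > len(records):
        raise ValueError(f"size {size} exceeds {len(records)} records")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(records), size=size, replace=False))
    return [records[i] for i in idx]


_EXPDTA = {"xray": "X-RAY DIFFRACTION", "nmr": "SOLUTION NMR",
           "em": "ELECTRON MICROSCOPY", "other": "THEORETICAL MODEL"}


def _flag_ranges(numbers: np.ndarray, flags: np.ndarray):
    """Contiguous runs of flagged residue numbers as (first, last) pairs."""
    runs, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((int(numbers[start]), int(numbers[i - 1])))
            start = None
    if start is not None:
        runs.append((int(numbers[start]), int(numbers[-1])))
    return runs


def write_fixture(chains, header: dict, path) -> Path:
    """Write one or more C-alpha chains as a standard PDB file (ATOM,
    HELIX/SHEET, REMARK 2, EXPDTA, KEYWDS records) that read_structure
    parses back to an equivalent record.

    `header` keys: entry_id, resolution (A or None), method, keywords.
    Helix/sheet records are emitted from the chains' own flags.
    """
    if isinstance(chains, CAlphaChain):
        chains = [chains]
    entry = str(header.get("entry_id", "XXXX"))[:4].upper().ljust(4)
    lines = [f"HEADER    {'SYNTHETIC CHAIN':<40}{'01-JAN-00':<9}   {entry}"]
    kw = header.get("keywords", "")
    if kw:
        lines.append(f"KEYWDS    {kw}")
    lines.append(f"EXPDTA    {_EXPDTA.get(header.get('method', 'xray'))}")
    res = header.get("resolution")
    if res is not None:
        lines.append(f"REMARK   2 RESOLUTION. {res:7.2f} ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")

    nhel = nstr = 0
    for ch in chains:
        for lo, hi in _flag_ranges(ch.residue_numbers, ch.helix_flag):
            nhel += 1
            i0 = int(np.searchsorted(ch.residue_numbers, lo))
            i1 = int(np.searchsorted(ch.residue_numbers, hi))
            lines.append(
                f"HELIX  {nhel:>3} {nhel:>3} {ch.residue_names[i0]:>3} "
                f"{ch.chain_id:1}{lo:>5}  {ch.residue_names[i1]:>3} "
                f"{ch.chain_id:1}{hi:>5}  1{'':30}{hi - lo + 1:>6}"
            )
        for lo, hi in _flag_ranges(ch.residue_numbers, ch.sheet_flag):
            nstr += 1
            i0 = int(np.searchsorted(ch.residue_numbers, lo))
            i1 = int(np.searchsorted(ch.residue_numbers, hi))
            lines.append(
                f"SHEET  {nstr:>3} S{nstr:<2} 1 {ch.residue_names[i0]:>3} "
                f"{ch.chain_id:1}{lo:>4}  {ch.residue_names[i1]:>3} "
                f"{ch.chain_id:1}{hi:>4}  0"
            )

    serial = 0
    for ch in chains:
        for num, name, (x, y, z) in zip(
            ch.residue_numbers, ch.residue_names, ch.coords
        ):
            serial += 1
            lines.append(
                f"ATOM  {serial:>5}  CA  {name:<3} {ch.chain_id:1}{num:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        serial += 1
        lines.append(f"TER   {serial:>5}      {ch.residue_names[-1]:>3} "
                     f"{ch.chain_id:1}{int(ch.residue_numbers[-1]):>4}")
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_entry_list(records, path) -> Path:
    """Plain-text entry list, one 'ID_chain' per line."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            for ch in rec.chains:
                fh.write(f"{rec.entry_id}_{ch.chain_id}\n")
    return path
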