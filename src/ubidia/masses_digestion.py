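"""In-silico tryptic digestion, modified-peptide enumeration and mass arithmetic.

The search space for a DIA ubiquitinomics experiment is the set of
tryptic peptides carrying a di-glycine (K-GG) remnant on internal
lysines, together with the standard variable modifications (Met
oxidation, protein N-terminal acetylation) and fixed
carbamidomethylation of cysteines.  All masses are monoisotopic and
derived from atomic composition via :mod:`pyteomics.mass`; modification
deltas are computed from their molecular formulas, never hard-coded per
peptide.

Key biochemical constraint: a lysine carrying the K-GG remnant is not
cleaved by trypsin, so every K-GG peptide necessarily carries at least
one missed cleavage and the remnant never sits on a peptide's
C-terminal residue.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "MOD_FORMULAS",
    "MOD_DELTAS",
    "ProteinEntry",
    "ModifiedPeptide",
    "FragmentAnnotation",
    "Precursor",
    "read_fasta",
    "digest",
    "enumerate_modified_forms",
    "neutral_mass",
    "precursor_mz",
    "fragment_mz",
    "select_fragments",
    "build_search_space",
    "write_search_space",
]

# Monoisotopic constants, all derived from one atomic-composition table
# (pyteomics NIST masses).  The proton is the hydrogen atom minus the
# electron, as required for m/z arithmetic of positive ions.
_ELECTRON = 0.00054857990907
PROTON_MASS = _pmass.calculate_mass(formula="H") - _ELECTRON
WATER_MASS = _pmass.calculate_mass(formula="H2O")
RESIDUE_MASSES: dict[str, float] = dict(_pmass.std_aa_mass)

CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

# Variable/fixed modification chemistry.  KGG is the di-glycine remnant
# left on a ubiquitinated lysine after tryptic digestion (two glycyl
# residues, C4H6N2O2 = 114.04293 Da).
MOD_FORMULAS: dict[str, str] = {
    "KGG": "C4H6N2O2",   # di-glycine remnant on K
    "CAM": "C2H3NO",     # carbamidomethyl on C (fixed)
    "OxM": "O",          # oxidation on M
    "NtAc": "C2H2O",     # protein N-terminal acetylation
}
MOD_DELTAS: dict[str, float] = {
    name: _pmass.calculate_mass(formula=f) for name, f in MOD_FORMULAS.items()
}
MOD_TARGET_RESIDUE = {"KGG": "K", "CAM": "C", "OxM": "M"}


@dataclass(frozen=True)
class ProteinEntry:
    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = [
            (i + 1, aa)
            for i, aa in enumerate(self.sequence)
            if aa not in CANONICAL_RESIDUES
        ]
        if bad:
            pos, aa = bad[0]
            raise ValueError(
                f"{self.accession}: non-canonical residue {aa!r} at position {pos}"
            )


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications.

    ``modifications`` holds ``(position_1based, mod_name, delta_mass)``
    tuples; CAM entries are present explicitly for every cysteine.
    """

    sequence: str
    protein_links: tuple[tuple[str, int], ...] = ()
    modifications: tuple[tuple[int, str, float], ...] = ()
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for pos, name, _ in self.modifications:
            if not 1 <= pos <= n:
                raise ValueError(f"mod position {pos} outside peptide of length {n}")
            target = MOD_TARGET_RESIDUE.get(name)
            if target is not None and self.sequence[pos - 1] != target:
                raise ValueError(
                    f"{name} at position {pos} but residue is "
                    f"{self.sequence[pos - 1]!r}"
                )
            if name == "KGG" and pos == n:
                raise ValueError("KGG on the C-terminal residue is not allowed")
        # the cap counts search-space variable mods only, not bookkeeping
        # entries such as the decoy collision mass shift
        n_var = sum(
            1 for _, name, _ in self.modifications if name in ("KGG", "OxM", "NtAc")
        )
        if n_var > 2:
            raise ValueError(f"{n_var} variable modifications exceed the cap of 2")

    @property
    def kgg_positions(self) -> tuple[int, ...]:
        return tuple(p for p, name, _ in self.modifications if name == "KGG")

    @property
    def mod_string(self) -> str:
        return ";".join(f"{name}@{pos}" for pos, name, _ in sorted(self.modifications))

    @property
    def peptide_id(self) -> str:
        return f"{self.sequence}[{self.mod_string}]" if self.modifications else self.sequence


@dataclass(frozen=True)
class FragmentAnnotation:
    series: str                 # 'b' or 'y'
    index: int
    charge: int
    mz: float
    contains_mod_site: bool
    contains_other_candidate_site: bool

    @property
    def fragment_id(self) -> str:
        return f"{self.series}{self.index}^{self.charge}"

    @property
    def sort_key(self) -> tuple[str, int, int]:
        # deterministic tie-break order: b before y, then index, then charge
        return (self.series, self.index, self.charge)


@dataclass(frozen=True)
class Precursor:
    peptide: ModifiedPeptide
    charge: int
    mz: float
    fragment_annotations: tuple[FragmentAnnotation, ...] = ()
    decoy: bool = False

    @property
    def precursor_id(self) -> str:
        tag = "DECOY-" if self.decoy else ""
        return f"{tag}{self.peptide.peptide_id}/{self.charge}"


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------

def _parse_accession(header: str) -> str:
    """UniProt dialect ``db|ACC|NAME``; plain headers fall back to token 1."""
    first = header.split()[0]
    parts = first.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return first


def read_fasta(path) -> list[ProteinEntry]:
    from Bio import SeqIO

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entries.append(
            ProteinEntry(
                accession=_parse_accession(rec.description),
                sequence=str(rec.seq).upper(),
                description=rec.description,
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def digest(
    protein: ProteinEntry,
    max_missed: int = 1,
    min_length: int | None = None,
    max_length: int | None = None,
) -> list[tuple[str, int]]:
    """Trypsin/P digestion: cleave C-terminal to K or R, including before P.

    Returns ``(span_sequence, start_position_1based)`` tuples for every
    contiguous span between cleavage sites with at most ``max_missed``
    internal sites, with an optional length filter applied afterwards.
    """
    seq = protein.sequence
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    # cut points after each K/R (trypsin/P: no proline exception)
    cuts = [0] + [i + 1 for i, aa in enumerate(seq) if aa in "KR"]
    if cuts[-1] != len(seq):
        cuts.append(len(seq))
    spans: list[tuple[str, int]] = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            lo, hi = cuts[i], cuts[j]
            span = seq[lo:hi]
            if min_length is not None and len(span) < min_length:
                continue
            if max_length is not None and len(span) > max_length:
                continue
            spans.append((span, lo + 1))
    return spans


def _missed_cleavages(span: str) -> int:
    # internal K/R (the C-terminal one, if any, is the cleavage site itself)
    return sum(1 for aa in span[:-1] if aa in "KR")


def enumerate_modified_forms(
    span: str,
    start: int = 1,
    accession: str | None = None,
    protein_length: int | None = None,
    variable_mods: tuple[str, ...] = ("KGG", "OxM", "NtAc"),
    max_variable: int = 2,
) -> list[ModifiedPeptide]:
    """All modified forms of one digestion span.

    CAM is applied to every cysteine unconditionally.  Variable
    candidates: KGG on every non-C-terminal K, OxM on every M, NtAc on
    the peptide N-terminus for spans starting at protein position 1 or 2
    (Met-cleavage convention).  At most ``max_variable`` variable mods
    per form.
    """
    n = len(span)
    fixed = tuple(
        (i + 1, "CAM", MOD_DELTAS["CAM"]) for i, aa in enumerate(span) if aa == "C"
    )
    candidates: list[tuple[int, str]] = []
    if "KGG" in variable_mods:
        candidates += [(i + 1, "KGG") for i, aa in enumerate(span[:-1]) if aa == "K"]
    if "OxM" in variable_mods:
        candidates += [(i + 1, "OxM") for i, aa in enumerate(span) if aa == "M"]
    if "NtAc" in variable_mods and start in (1, 2):
        candidates.append((1, "NtAc"))

    links = ((accession, start),) if accession else ()
    mc = _missed_cleavages(span)
    forms: list[ModifiedPeptide] = []
    seen: set[tuple] = set()
    for r in range(0, max_variable + 1):
        for combo in itertools.combinations(candidates, r):
            # NtAc sits on the alpha-amine, so it may coexist with a
            # side-chain mod on residue 1; side-chain mods may not stack
            positions = [0 if name == "NtAc" else p for p, name in combo]
            if len(set(positions)) != len(positions):
                continue
            mods = fixed + tuple(
                (p, name, MOD_DELTAS[name]) for p, name in sorted(combo)
            )
            key = tuple(sorted((p, name) for p, name, _ in mods))
            if key in seen:
                continue
            seen.add(key)
            forms.append(
                ModifiedPeptide(
                    sequence=span,
                    protein_links=links,
                    modifications=mods,
                    missed_cleavages=mc,
                )
            )
    return forms


# ---------------------------------------------------------------------------
# Mass arithmetic
# ---------------------------------------------------------------------------

def neutral_mass(p: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass: residues + water + modification deltas."""
    try:
        total = sum(RESIDUE_MASSES[aa] for aa in p.sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {p.sequence}") from exc
    return total + WATER_MASS + sum(d for _, _, d in p.modifications)


def precursor_mz(p: ModifiedPeptide, charge: int) -> float:
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass(p) + charge * PROTON_MASS) / charge


def fragment_mz(
    p: ModifiedPeptide, series: str, index: int, charge: int = 1
) -> tuple[float, FragmentAnnotation]:
    """m/z and site annotation of one b/y fragment.

    ``contains_mod_site`` is true iff a KGG-modified position lies in
    the fragment's residue span; ``contains_other_candidate_site`` is
    true iff an unmodified, non-C-terminal K (a potential remnant site)
    lies in the span.
    """
    n = len(p.sequence)
    if not 1 <= index <= n - 1:
        raise ValueError(f"fragment index {index} out of range for length {n}")
    if series == "b":
        span = range(1, index + 1)
        base = 0.0
    elif series == "y":
        span = range(n - index + 1, n + 1)
        base = WATER_MASS
    else:
        raise ValueError(f"unknown ion series {series!r}")
    span_set = set(span)
    residue_sum = sum(RESIDUE_MASSES[p.sequence[i - 1]] for i in span)
    mod_sum = sum(d for pos, name, d in p.modifications if pos in span_set
                  or (name == "NtAc" and series == "b"))
    mz = (residue_sum + base + mod_sum + charge * PROTON_MASS) / charge

    kgg = set(p.kgg_positions)
    other_sites = {
        i + 1
        for i, aa in enumerate(p.sequence[:-1])
        if aa == "K" and (i + 1) not in kgg
    }
    ann = FragmentAnnotation(
        series=series,
        index=index,
        charge=charge,
        mz=mz,
        contains_mod_site=bool(kgg & span_set),
        contains_other_candidate_site=bool(other_sites & span_set),
    )
    return mz, ann


def select_fragments(
    p: ModifiedPeptide,
    max_per_series: int = 5,
    min_index: int = 2,
    charge: int = 1,
) -> tuple[FragmentAnnotation, ...]:
    """Deterministic fragment panel for scoring.

    Up to ``max_per_series`` b and y ions, indices spread evenly over
    ``min_index .. n-1`` so that the panel mixes fragments that do and
    do not cover the modified residue.
    """
    import numpy as np

    n = len(p.sequence)
    hi = n - 1
    if hi < min_index:
        idx = [hi] if hi >= 1 else []
    else:
        idx = sorted(
            set(np.linspace(min_index, hi, num=min(max_per_series, hi - min_index + 1))
                .round().astype(int).tolist())
        )
    anns = []
    for series in ("b", "y"):
        for i in idx:
            anns.append(fragment_mz(p, series, i, charge)[1])
    return tuple(sorted(anns, key=lambda a: a.sort_key))


# ---------------------------------------------------------------------------
# Search-space construction
# ---------------------------------------------------------------------------

def build_search_space(
    proteins: list[ProteinEntry],
    config=None,
    kgg_only: bool = True,
) -> list[Precursor]:
    """Digest, enumerate modified forms, and attach fragment panels.

    With ``kgg_only`` (the ubiquitinomics search) only forms carrying at
    least one K-GG remnant are kept.  Identical peptide forms arising
    from multiple proteins are merged, accumulating protein links.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    by_key: dict[tuple, ModifiedPeptide] = {}
    for prot in proteins:
        spans = digest(
            prot,
            max_missed=cfg.max_missed_cleavages + 1,  # KGG blocks one K site
            min_length=cfg.min_peptide_length,
            max_length=cfg.max_peptide_length,
        )
        for span, start in spans:
            for form in enumerate_modified_forms(
                span, start, prot.accession, len(prot.sequence),
                max_variable=cfg.max_variable_mods,
            ):
                if kgg_only and not form.kgg_positions:
                    continue
                # enforce the engine missed-cleavage budget after discounting
                # cleavage sites blocked by the remnant
                effective_mc = form.missed_cleavages - len(form.kgg_positions)
                if effective_mc > cfg.max_missed_cleavages:
                    continue
                key = (form.sequence, tuple((p, n) for p, n, _ in form.modifications))
                if key in by_key:
                    prev = by_key[key]
                    by_key[key] = ModifiedPeptide(
                        sequence=prev.sequence,
                        protein_links=tuple(
                            sorted(set(prev.protein_links) | set(form.protein_links))
                        ),
                        modifications=prev.modifications,
                        missed_cleavages=prev.missed_cleavages,
                    )
                else:
                    by_key[key] = form

    precursors = []
    for form in by_key.values():
        frags = select_fragments(
            form,
            max_per_series=cfg.max_fragments_per_series,
            min_index=cfg.min_fragment_index,
            charge=cfg.fragment_charge,
        )
        for z in cfg.precursor_charges:
            precursors.append(
                Precursor(
                    peptide=form,
                    charge=z,
                    mz=precursor_mz(form, z),
                    fragment_annotations=frags,
                )
            )
    precursors.sort(key=lambda pr: pr.precursor_id)
    return precursors


def write_search_space(precursors: list[Precursor], path, header_lines=()) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["peptide", "mods", "charge", "precursor_mz", "protein_links",
                    "missed_cleavages", "decoy"])
        for pr in precursors:
            pep = pr.peptide
            w.writerow([
                pep.sequence,
                pep.mod_string,
                pr.charge,
                f"{pr.mz:.6f}",
                ";".join(f"{acc}@{pos}" for acc, pos in pep.protein_links),
                pep.missed_cleavages,
                int(pr.decoy),
            ])
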