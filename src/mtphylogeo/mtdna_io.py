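"""Haplotype notation, sequence conversion, sample tables, and haplogroup assignment.

Human mtDNA haplotypes are conventionally written as lists of differences from
the revised Cambridge Reference Sequence (rCRS), e.g. ``16343`` (transition),
``6515G`` (transversion to G), ``15944dT`` (deletion of a T run), ``523.1CA``
(insertion of CA after np 523), and ``@16223`` (back-mutation restoring the
reference state).  This module parses and formats that notation, converts
haplotypes to sequences and back against a reference window, reads and writes
FASTA and delimited sample tables, and assigns haplotypes to haplogroups by
cumulative diagnostic motifs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import pandas as pd

RCRS_LENGTH = 16569

#: Transition partners on the four-letter alphabet (purines, pyrimidines).
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: Control-region positions of notoriously unstable sites, shipped as default
#: down-weight candidates for network building (never silently dropped).
DEFAULT_UNSTABLE_SITES = (16182, 16183, 16519, 523, 524)

#: Default hypervariable-segment windows (1-based, inclusive).
HVSI_WINDOW = (16024, 16383)
HVSII_WINDOW = (57, 372)


class MutationParseError(ValueError):
    """Raised for tokens that do not match the mutation grammar."""


class MutationRangeError(ValueError):
    """Raised for positions outside 1..16569."""


class SequenceConsistencyError(ValueError):
    """Raised when a mutation contradicts the reference it is applied to."""


_TOKEN_RE = re.compile(
    r"""^(?P<back>@?)
        (?P<pos>\d+)
        (?:
            (?P<trv>[ACGT]+)            # transversion derived base(s)
          | d(?P<del>[ACGT]+)           # deletion of a named run
          | \.(?P<idx>\d+)(?P<ins>[ACGT]+)   # insertion after the position
        )?$""",
    re.VERBOSE,
)


@dataclass(frozen=True, order=True)
class Mutation:
    """One rCRS-relative change: the atom of haplotypes and branch labels.

    ``kind`` is one of ``transition``, ``transversion``, ``deletion``,
    ``insertion``.  Transitions carry no explicit derived base (the partner of
    the reference base is implied).  ``back`` flags a reversion written with
    the ``@`` prefix.
    """

    position: int
    kind: str = "transition"
    derived: str = ""
    deleted: str = ""
    ins_index: int = 0
    back: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.position <= RCRS_LENGTH):
            raise MutationRangeError(
                f"position {self.position} outside rCRS range 1..{RCRS_LENGTH}"
            )
        if self.kind not in ("transition", "transversion", "deletion", "insertion"):
            raise MutationParseError(f"unknown mutation kind {self.kind!r}")

    def __str__(self) -> str:
        return format_mutation(self)


def parse_mutation(token: str, hvs_shorthand: bool = False) -> Mutation:
    """Parse one mutation token.

    With ``hvs_shorthand``, a bare 1-3 digit token is offset by +16000 — the
    compact control-region convention in which ``343`` means np 16343.
    """
    token = token.strip()
    m = _TOKEN_RE.match(token)
    if m is None:
        raise MutationParseError(f"malformed mutation token {token!r}")
    pos = int(m.group("pos"))
    if hvs_shorthand and m.group("pos").lstrip("0") and len(m.group("pos")) <= 3:
        pos += 16000
    back = bool(m.group("back"))
    if m.group("trv"):
        return Mutation(pos, "transversion", derived=m.group("trv"), back=back)
    if m.group("del"):
        return Mutation(pos, "deletion", deleted=m.group("del"), back=back)
    if m.group("ins"):
        return Mutation(
            pos, "insertion", derived=m.group("ins"), ins_index=int(m.group("idx")), back=back
        )
    return Mutation(pos, "transition", back=back)


def format_mutation(mut: Mutation) -> str:
    """Canonical text form; ``parse_mutation(format_mutation(m)) == m``."""
    prefix = "@" if mut.back else ""
    if mut.kind == "transition":
        return f"{prefix}{mut.position}"
    if mut.kind == "transversion":
        return f"{prefix}{mut.position}{mut.derived}"
    if mut.kind == "deletion":
        return f"{prefix}{mut.position}d{mut.deleted}"
    return f"{prefix}{mut.position}.{mut.ins_index}{mut.derived}"


def parse_haplotype_tokens(
    tokens: Iterable[str] | str, hvs_shorthand: bool = False
) -> tuple[Mutation, ...]:
    if isinstance(tokens, str):
        tokens = tokens.split()
    muts = tuple(sorted(parse_mutation(t, hvs_shorthand) for t in tokens))
    seen: set[tuple[int, str]] = set()
    for m in muts:
        key = (m.position, m.kind)
        if key in seen:
            raise MutationParseError(
                f"duplicate mutation at position {m.position} ({m.kind}); "
                "a reversion must be written with '@'"
            )
        seen.add(key)
    return muts


@dataclass(frozen=True)
class Haplotype:
    """A sample's mutation set relative to the reference, plus its labels."""

    mutations: tuple[Mutation, ...]
    sample_id: str = ""
    region: str = ""
    population: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutations", tuple(sorted(self.mutations)))

    @classmethod
    def from_tokens(
        cls,
        tokens: Iterable[str] | str,
        sample_id: str = "",
        region: str = "",
        population: str = "",
        hvs_shorthand: bool = False,
    ) -> "Haplotype":
        return cls(parse_haplotype_tokens(tokens, hvs_shorthand), sample_id, region, population)

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(format_mutation(m) for m in self.mutations)

    def key(self) -> str:
        """Haplotype identity key: the sorted canonical token string."""
        return " ".join(self.tokens)


@dataclass(frozen=True)
class HaplogroupDef:
    """PhyloTree-style clade definition: name, parent, diagnostic motif."""

    name: str
    parent: str | None
    motif: tuple[Mutation, ...]


@dataclass(frozen=True)
class ReferenceSequence:
    """A 16,569-bp reference (rCRS numbering, 1-based)."""

    bases: str
    name: str = "rCRS"

    def __post_init__(self) -> None:
        if len(self.bases) != RCRS_LENGTH:
            raise ValueError(
                f"reference must be {RCRS_LENGTH} bp, got {len(self.bases)}"
            )
        object.__setattr__(self, "bases", self.bases.upper())

    def base(self, position: int) -> str:
        return self.bases[position - 1]


def load_reference(path: str | Path | None = None) -> ReferenceSequence:
    """Load a reference FASTA; default is the packaged synthetic stand-in.

    The bundled ``synthetic_rcrs.fasta`` is a deterministic synthetic sequence
    of rCRS length with 'N' kept at np 3107 (the historical placeholder).  It
    exercises every coordinate convention; for work on real data supply the
    actual rCRS FASTA here.
    """
    if path is None:
        ref_dir = resources.files("mtphylogeo") / "data" / "synthetic_rcrs.fasta"
        with resources.as_file(ref_dir) as p:
            rec = next(SeqIO.parse(str(p), "fasta"))
    else:
        rec = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceSequence(str(rec.seq), rec.id)


# ---------------------------------------------------------------------------
# haplotype <-> sequence


def _validate_against_reference(mut: Mutation, ref: ReferenceSequence) -> None:
    if mut.kind == "transversion" and not mut.back:
        ref_base = ref.base(mut.position)
        if mut.derived in (ref_base, TRANSITION_PARTNER.get(ref_base)):
            raise SequenceConsistencyError(
                f"transversion {format_mutation(mut)}: derived base equals the "
                f"reference base or its transition partner ({ref_base})"
            )
    if mut.kind == "deletion" and not mut.back:
        run = ref.bases[mut.position - 1 : mut.position - 1 + len(mut.deleted)]
        if run != mut.deleted:
            raise SequenceConsistencyError(
                f"deletion {format_mutation(mut)}: reference carries {run!r} at "
                f"np {mut.position}"
            )


def haplotype_to_sequence(
    hap: Haplotype | Sequence[Mutation],
    ref: ReferenceSequence,
    window: tuple[int, int] | None = None,
    as_alignment: bool = False,
):
    """Apply a haplotype's mutations to the reference window.

    Returns the mutated sequence as a plain string; with ``as_alignment`` a
    ``(seq, ref)`` pair of equal-length gapped strings ('-' opposite deletions
    and insertions) suitable for lossless round-tripping through
    :func:`sequence_to_haplotype`.  Back-mutations restore the reference state
    and therefore leave the output unchanged.
    """
    muts = hap.mutations if isinstance(hap, Haplotype) else tuple(hap)
    lo, hi = window if window is not None else (1, RCRS_LENGTH)
    seq_cols = list(ref.bases[lo - 1 : hi])
    ref_cols = list(ref.bases[lo - 1 : hi])
    inserts: dict[int, str] = {}
    for mut in sorted(muts):
        if not (lo <= mut.position <= hi):
            raise ValueError(
                f"mutation {format_mutation(mut)} outside window {lo}-{hi}"
            )
        _validate_against_reference(mut, ref)
        if mut.back:
            continue  # reversion: reference state stands
        i = mut.position - lo
        if mut.kind == "transition":
            seq_cols[i] = TRANSITION_PARTNER.get(ref.base(mut.position), "N")
        elif mut.kind == "transversion":
            seq_cols[i] = mut.derived
        elif mut.kind == "deletion":
            for j in range(len(mut.deleted)):
                seq_cols[i + j] = "-"
        elif mut.kind == "insertion":
            inserts[i] = mut.derived
    # splice insertions (after the anchor column), keeping both rows aligned
    if inserts:
        out_seq: list[str] = []
        out_ref: list[str] = []
        for i, (s, r) in enumerate(zip(seq_cols, ref_cols)):
            out_seq.append(s)
            out_ref.append(r)
            if i in inserts:
                out_seq.append(inserts[i])
                out_ref.append("-" * len(inserts[i]))
        seq_cols, ref_cols = out_seq, out_ref
    seq_aln = "".join(seq_cols)
    ref_aln = "".join(ref_cols)
    if as_alignment:
        return seq_aln, ref_aln
    return seq_aln.replace("-", "")


def sequence_to_haplotype(
    seq: str,
    ref: ReferenceSequence,
    window: tuple[int, int] | None = None,
    ref_aligned: str | None = None,
    sample_id: str = "",
    region: str = "",
) -> Haplotype:
    """Infer the minimal mutation set of ``seq`` relative to the reference.

    Without ``ref_aligned`` the sequence must equal the window length
    (substitutions only; '-' columns are read as deletions).  For insertions
    pass the gapped reference row produced by ``haplotype_to_sequence(...,
    as_alignment=True)``.
    """
    lo, hi = window if window is not None else (1, RCRS_LENGTH)
    seq = seq.upper()
    if ref_aligned is None:
        ref_aligned = ref.bases[lo - 1 : hi]
        if len(seq) != len(ref_aligned):
            raise ValueError(
                f"sequence length {len(seq)} != window length {len(ref_aligned)}; "
                "pass an aligned pair for indels"
            )
    elif len(seq) != len(ref_aligned):
        raise ValueError("aligned pair rows differ in length")
    ref_aligned = ref_aligned.upper()

    muts: list[Mutation] = []
    pos = lo - 1  # last reference position consumed
    i = 0
    n = len(seq)
    while i < n:
        r, s = ref_aligned[i], seq[i]
        if r == "-":
            # insertion run after `pos`
            j = i
            while j < n and ref_aligned[j] == "-":
                j += 1
            muts.append(Mutation(pos, "insertion", derived=seq[i:j], ins_index=1))
            i = j
            continue
        pos += 1
        if s == "-":
            j = i
            p = pos
            run = []
            while j < n and seq[j] == "-" and ref_aligned[j] != "-":
                run.append(ref_aligned[j])
                j += 1
            muts.append(Mutation(p, "deletion", deleted="".join(run)))
            pos += len(run) - 1
            i = j
            continue
        if s != r and r != "N" and s != "N":
            if s == TRANSITION_PARTNER.get(r):
                muts.append(Mutation(pos, "transition"))
            else:
                muts.append(Mutation(pos, "transversion", derived=s))
        i += 1
    return Haplotype(tuple(sorted(muts)), sample_id=sample_id, region=region)


# ---------------------------------------------------------------------------
# haplogroup assignment


def cumulative_motif(
    name: str, defs: Mapping[str, HaplogroupDef]
) -> tuple[Mutation, ...]:
    """Root-to-clade accumulated motif; a child's ``@x`` cancels an ancestral x."""
    chain: list[HaplogroupDef] = []
    cur: str | None = name
    seen = set()
    while cur is not None:
        if cur in seen:
            raise ValueError(f"haplogroup definitions contain a parent cycle at {cur}")
        seen.add(cur)
        d = defs[cur]
        chain.append(d)
        cur = d.parent
    acc: dict[tuple[int, str], Mutation] = {}
    for d in reversed(chain):
        for m in d.motif:
            key = (m.position, m.kind)
            if m.back and key in acc and not acc[key].back:
                del acc[key]  # reversion cancels the ancestral gain
            else:
                acc[key] = m
    return tuple(sorted(acc.values()))


@dataclass(frozen=True)
class AssignmentReport:
    haplogroup: str
    matched: tuple[Mutation, ...]
    missing: tuple[Mutation, ...]
    private: tuple[Mutation, ...]
    fraction: float
    warning: bool = False


def assign_haplogroup(
    hap: Haplotype,
    defs: Sequence[HaplogroupDef],
    min_motif_fraction: float = 1.0,
) -> AssignmentReport:
    """Deepest clade whose cumulative motif is matched at >= ``min_motif_fraction``.

    Ties (equal depth and fraction) are broken by fewest private mutations,
    then lexicographic name.  If no clade reaches the threshold the forest
    root is returned with a warning flag.
    """
    if not defs:
        raise ValueError("empty haplogroup definition set")
    by_name = {d.name: d for d in defs}
    hap_set = set(hap.mutations)

    def depth(name: str) -> int:
        d, k = by_name[name], 0
        while d.parent is not None:
            d = by_name[d.parent]
            k += 1
        return k

    best: tuple | None = None
    for d in defs:
        motif = cumulative_motif(d.name, by_name)
        matched = tuple(m for m in motif if m in hap_set)
        if not motif:
            frac = 1.0
        else:
            frac = len(matched) / len(motif)
        if frac < min_motif_fraction:
            continue
        missing = tuple(m for m in motif if m not in hap_set)
        private = tuple(sorted(hap_set - set(motif)))
        cand = (-depth(d.name), -frac, len(private), d.name)
        if best is None or cand < best[0]:
            best = (cand, d, matched, missing, private, frac)
    if best is None:
        roots = sorted(d.name for d in defs if d.parent is None)
        root = roots[0]
        motif = cumulative_motif(root, by_name)
        matched = tuple(m for m in motif if m in hap_set)
        return AssignmentReport(
            root,
            matched,
            tuple(m for m in motif if m not in hap_set),
            tuple(sorted(hap_set - set(motif))),
            len(matched) / len(motif) if motif else 1.0,
            warning=True,
        )
    _, d, matched, missing, private, frac = best
    # a vacuous match (empty cumulative motif, i.e. the bare forest root)
    # carries the same warning as a below-threshold fallback
    return AssignmentReport(d.name, matched, missing, private, frac,
                            warning=len(matched) + len(missing) == 0)


# ---------------------------------------------------------------------------
# file I/O


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]], path: str | Path) -> None:
    recs = [
        r if isinstance(r, SeqRecord) else SeqRecord(Seq(r[1]), id=r[0], description="")
        for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


SAMPLE_COLUMNS = ["sample_id", "region", "population", "haplotype"]


def read_sample_table(
    path: str | Path,
    hvs_shorthand: bool = False,
    allowed_regions: Sequence[str] | None = None,
    sep: str | None = None,
) -> list[Haplotype]:
    """Read a delimited sample table (TSV default; comma accepted).

    Columns: sample_id, region, population, haplotype (space-separated mutation
    tokens; empty for the reference haplotype).
    """
    if sep is None:
        head = Path(path).read_text().splitlines()[0]
        sep = "," if ("," in head and "\t" not in head) else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
    if allowed_regions is not None:
        bad = sorted(set(df["region"]) - set(allowed_regions))
        if bad:
            raise ValueError(
                f"unknown regions {bad}; allowed regions: {sorted(allowed_regions)}"
            )
    return [
        Haplotype.from_tokens(
            row.haplotype, row.sample_id, row.region, row.population, hvs_shorthand
        )
        for row in df.itertuples()
    ]


def write_sample_table(haps: Iterable[Haplotype], path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": h.sample_id,
                "region": h.region,
                "population": h.population,
                "haplotype": " ".join(h.tokens),
            }
            for h in haps
        ],
        columns=SAMPLE_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)


def read_haplogroup_defs(path: str | Path, hvs_shorthand: bool = False) -> list[HaplogroupDef]:
    """Haplogroup definitions as TSV: name, parent (empty for roots), motif tokens."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        HaplogroupDef(
            row["name"],
            row["parent"] or None,
            parse_haplotype_tokens(row["motif"], hvs_shorthand),
        )
        for _, row in df.iterrows()
    ]


def write_haplogroup_defs(defs: Iterable[HaplogroupDef], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "name": d.name,
                "parent": d.parent or "",
                "motif": " ".join(format_mutation(m) for m in d.motif),
            }
            for d in defs
        ]
    )
    df.to_csv(path, sep="\t", index=False)
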