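"""Readers and writers for the plain-text formats the pipeline touches.

FASTA (strict: 60-column wrap on write, lowercase tolerated and uppercased
on read, ``*`` rejected, parse errors carry line numbers), hit-table and
score-table TSV, profile TSV, benchmark CSVs and the YAML/JSON pipeline
configuration.  Coordinates are 0-based half-open in memory and 1-based
closed in every file; the converters live here and nowhere else.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .alphabet import AA, AA_SET, N_AA
from .align import Hit, HitTable
from .errors import AlphabetError, ParseError
from .fragsim import Fragment, FragmentSet, ProteomeDB, ProteomeRecord
from .identify import DLST_EXCEPTION_TERMS, DLST_MATCH_TERMS, MISSING_TOKEN, MatchScore

FASTA_WIDTH = 60
_VALID_CHARS = AA_SET | {"X"}


@dataclass
class FastaRecord:
    id: str
    description: str
    sequence: str


def read_fasta(path) -> list[FastaRecord]:
    """Parse a FASTA file strictly.

    The id is the first whitespace token after ``>``; the rest of the header
    is the description.  Sequences are uppercased; blank lines are
    tolerated; text before the first header, empty ids, empty sequences,
    ``*`` and non-residue characters are errors with line numbers.
    """
    records: list[FastaRecord] = []
    cur: FastaRecord | None = None
    cur_line = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur is not None and not cur.sequence:
                    raise ParseError(f"record {cur.id!r} has no sequence", cur_line)
                header = line[1:].strip()
                if not header:
                    raise ParseError("empty FASTA header", lineno)
                parts = header.split(None, 1)
                cur = FastaRecord(parts[0], parts[1] if len(parts) > 1 else "", "")
                cur_line = lineno
                records.append(cur)
            else:
                if cur is None:
                    raise ParseError("sequence data before the first '>' header", lineno)
                chunk = line.upper()
                bad = set(chunk) - _VALID_CHARS
                if bad:
                    raise AlphabetError(
                        f"line {lineno}: invalid sequence character(s) "
                        f"{''.join(sorted(bad))!r} in record {cur.id!r}"
                    )
                cur.sequence += chunk
    if cur is not None and not cur.sequence:
        raise ParseError(f"record {cur.id!r} has no sequence", cur_line)
    return records


def write_fasta(records, path, width: int = FASTA_WIDTH) -> None:
    """Write (id, description, sequence) records wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            rid = getattr(rec, "id", None) or rec[0]
            desc = getattr(rec, "description", None)
            seq = getattr(rec, "sequence", None)
            if desc is None and seq is None:
                _, desc, seq = rec
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fragments_fasta(fragset: FragmentSet, path) -> None:
    """Fragments as FASTA; headers carry resolution/span/seed key=value pairs
    (spans 1-based closed, as in all human-readable output)."""
    prov = fragset.provenance
    recs = []
    for f in fragset:
        fields = []
        if "resolution" in prov:
            fields.append(f"resolution={prov['resolution']:g}")
        if f.source_span is not None:
            s, e = f.source_span
            fields.append(f"span={s + 1}-{e}")
        if "seed" in prov:
            fields.append(f"seed={prov['seed']}")
        recs.append(FastaRecord(f.id, " ".join(fields), f.sequence))
    write_fasta(recs, path)


def read_fragments_fasta(path) -> FragmentSet:
    records = read_fasta(path)
    frags = []
    prov: dict = {}
    for rec in records:
        kv = dict(p.split("=", 1) for p in rec.description.split() if "=" in p)
        span = None
        if "span" in kv:
            s, e = kv["span"].split("-")
            span = (int(s) - 1, int(e))
        if "resolution" in kv:
            prov["resolution"] = float(kv["resolution"])
        if "seed" in kv:
            prov["seed"] = int(kv["seed"])
        frags.append(Fragment(rec.id, rec.sequence, source_span=span))
    return FragmentSet(frags, provenance=prov)


def read_proteome_fasta(path) -> ProteomeDB:
    return ProteomeDB(
        [ProteomeRecord(r.id, r.description, r.sequence) for r in read_fasta(path)]
    )


def write_proteome_fasta(db: ProteomeDB, path) -> None:
    write_fasta(db.records, path)


def write_profile_tsv(profile: np.ndarray, path) -> None:
    """Per-position emission probabilities, 20 columns in alphabetical order."""
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(AA) + "\n")
        for i, row in enumerate(np.asarray(profile), start=1):
            fh.write(str(i) + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_profile_tsv(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[1:] != list(AA):
            raise ParseError("profile TSV must have the 20 residue columns in order", 1)
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != N_AA + 1:
                raise ParseError("wrong column count in profile TSV", lineno)
            rows.append([float(v) for v in parts[1:]])
    return np.array(rows)


HIT_COLUMNS = [
    "query_id", "subject_id", "description", "raw_score", "bit_score",
    "evalue", "q_start", "q_end", "s_start", "s_end",
]


def write_hit_table(table: HitTable, path) -> None:
    """Hit TSV, 1-based closed coordinates, E-values as 3-significant-digit
    scientific notation."""
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in table:
            fh.write(
                "\t".join(
                    [
                        table.query_id,
                        h.subject_id,
                        h.description,
                        f"{h.raw_score:g}",
                        f"{h.bit_score:.2f}",
                        f"{h.evalue:.2e}",
                        str(h.query_span[0] + 1),
                        str(h.query_span[1]),
                        str(h.subject_span[0] + 1),
                        str(h.subject_span[1]),
                    ]
                )
                + "\n"
            )


def read_hit_table(path) -> HitTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != HIT_COLUMNS:
            raise ParseError("unexpected hit-table header", 1)
        hits = []
        query_id = "query"
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(HIT_COLUMNS):
                raise ParseError("wrong column count in hit table", lineno)
            query_id = parts[0]
            hits.append(
                Hit(
                    subject_id=parts[1],
                    description=parts[2],
                    raw_score=float(parts[3]),
                    bit_score=float(parts[4]),
                    evalue=float(parts[5]),
                    query_span=(int(parts[6]) - 1, int(parts[7])),
                    subject_span=(int(parts[8]) - 1, int(parts[9])),
                )
            )
    return HitTable(query_id, hits)


def write_score_table(scores: list[MatchScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tn_entries\tn_matched\tscore\n")
        for s in scores:
            fh.write(f"{s.query_id}\t{s.n_entries}\t{s.n_matched}\t{s}\n")


def read_score_table(path) -> list[MatchScore]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["query_id", "n_entries", "n_matched", "score"]:
            raise ParseError("unexpected score-table header", 1)
        for lineno, line in enumerate(fh, start=2):
            q, n, m, v = line.rstrip("\n").split("\t")
            if v == MISSING_TOKEN:
                out.append(MatchScore.missing(q))
            else:
                out.append(MatchScore(q, float(v), int(n), int(m)))
    return out


def write_phmm(hmm, path) -> None:
    """Serialise a profile HMM as plain text (header + per-state blocks)."""
    with open(path, "w") as fh:
        fh.write("FRAGID-PHMM\t1\n")
        fh.write(f"length\t{hmm.length}\n")
        fh.write(f"alphabet\t{AA}\n")
        fh.write(f"glocal\t{int(hmm.glocal)}\n")
        fh.write("background\t" + "\t".join(f"{v:.8f}" for v in hmm.background) + "\n")
        for j in range(hmm.length):
            fh.write(f"state\t{j + 1}\n")
            fh.write("match\t" + "\t".join(f"{v:.8f}" for v in hmm.match_emissions[j]) + "\n")
            fh.write("t_match\t" + "\t".join(f"{v:.8f}" for v in hmm.t_match[j]) + "\n")
            fh.write("t_insert\t" + "\t".join(f"{v:.8f}" for v in hmm.t_insert[j]) + "\n")
            fh.write("t_delete\t" + "\t".join(f"{v:.8f}" for v in hmm.t_delete[j]) + "\n")


def read_phmm(path):
    from .phmm import ProfileHMM, _local_entry_exit

    def _renorm(a):  # undo the small rounding loss of the text format
        a = np.asarray(a)
        return a / a.sum(axis=-1, keepdims=True)

    with open(path) as fh:
        lines = [ln.rstrip("\n").split("\t") for ln in fh if ln.strip()]
    if not lines or lines[0][0] != "FRAGID-PHMM":
        raise ParseError("not a FRAGID-PHMM file", 1)
    header = {}
    i = 1
    while i < len(lines) and lines[i][0] != "state":
        header[lines[i][0]] = lines[i][1:]
        i += 1
    L = int(header["length"][0])
    glocal = bool(int(header.get("glocal", ["0"])[0]))
    bg = _renorm([float(v) for v in header["background"]])
    em = np.zeros((L, N_AA))
    tm = np.zeros((L, 3))
    ti = np.zeros((L, 2))
    td = np.zeros((L, 2))
    j = -1
    for parts in lines[i:]:
        key = parts[0]
        if key == "state":
            j = int(parts[1]) - 1
        elif key == "match":
            em[j] = [float(v) for v in parts[1:]]
        elif key == "t_match":
            tm[j] = [float(v) for v in parts[1:]]
        elif key == "t_insert":
            ti[j] = [float(v) for v in parts[1:]]
        elif key == "t_delete":
            td[j] = [float(v) for v in parts[1:]]
        else:
            raise ParseError(f"unexpected key {key!r} in profile file")
    entry, exitp = _local_entry_exit(L, glocal)
    return ProfileHMM(
        _renorm(em), bg.copy(), _renorm(tm), _renorm(ti), _renorm(td), bg, entry, exitp, glocal
    )


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline; round-trips through YAML losslessly."""

    # degradation model
    scale_k: float = 150.0
    error_base: float = 0.10
    error_slope: float = 0.08
    reference_resolution: float = 2.5
    coverage_multiple: float = 3.0
    # alignment
    matrix_name: str = "BLOSUM62"
    global_gap_open: float = 10.0
    global_gap_extend: float = 0.5
    end_gaps_free: bool = True
    local_gap_open: float = 11.0
    local_gap_extend: float = 1.0
    # search statistics
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    max_evalue: float = 10.0
    top_n: int = 100
    # consensus / profiles
    max_gap_fraction: float = 0.5
    pseudocount_alpha: float = 1.0
    n_null_shuffles: int = 200
    # identification terms
    match_terms: list = field(default_factory=lambda: list(DLST_MATCH_TERMS))
    exception_terms: list = field(default_factory=lambda: list(DLST_EXCEPTION_TERMS))
    # run
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        """Short stable hash of the resolved configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
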