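"""Format parsers and writers, plus the external-annotator adapter.

Formats handled: FASTA (via Biopython), 12-column tabular alignment output
(the BLAST/DIAMOND ``outfmt 6`` dialect), HMMER ``--tblout``, and the TSV
tables this package defines (host-lineage table, protein coordinate table,
truth table).  Coordinates are 1-based inclusive internally (GFF
convention); any conversion happens inside the parsers.

Parsers are streaming and tolerant: malformed rows are counted and logged,
and a file in which more than 10% of rows are malformed aborts with a
summary, since that usually means the wrong format was supplied.
"""

from __future__ import annotations

import datetime as _dt
import logging
import shlex
import subprocess
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .backbone import HostLineage
from .config import RANKS, PipelineConfig
from .encode import PlasmidContig, ProteinCall
from .vocab import AlignmentHit

logger = logging.getLogger(__name__)

MALFORMED_ABORT_FRACTION = 0.10


class MalformedFileError(ValueError):
    pass


def _check_malformed(path: Path, n_bad: int, n_total: int) -> None:
    if n_bad:
        logger.warning("%s: %d of %d rows malformed (skipped)", path, n_bad, n_total)
    if n_total and n_bad / n_total > MALFORMED_ABORT_FRACTION:
        raise MalformedFileError(
            f"{path}: {n_bad}/{n_total} rows malformed (> "
            f"{MALFORMED_ABORT_FRACTION:.0%}); wrong format?")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, uppercased sequence); tolerates CRLF and lowercase."""
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, str(record.seq).upper()


def write_fasta(records: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid in records:
            fh.write(f">{rid}\n")
            seq = records[rid]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# 12-column tabular alignment (outfmt-6 dialect)
# ---------------------------------------------------------------------------

def parse_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    """Parse qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore rows into AlignmentHit records."""
    path = Path(path)
    hits: list[AlignmentHit] = []
    n_bad = n_total = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_total += 1
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 12:
                n_bad += 1
                continue
            try:
                hits.append(AlignmentHit(query_id=fields[0], subject_id=fields[1],
                                         evalue=float(fields[10]),
                                         bitscore=float(fields[11])))
            except ValueError:
                n_bad += 1
    _check_malformed(path, n_bad, n_total)
    return hits


def write_tabular_hits(rows: Sequence[tuple[str, str, float, float]],
                       path: str | Path) -> None:
    """Write (query, subject, evalue, bitscore) as 12-column rows; the
    positional columns are filled with placeholder alignments."""
    with open(path, "w") as fh:
        for q, s, ev, bs in rows:
            fh.write(f"{q}\t{s}\t100.0\t100\t0\t0\t1\t100\t1\t100\t{ev:g}\t{bs:g}\n")


# ---------------------------------------------------------------------------
# HMMER --tblout
# ---------------------------------------------------------------------------

def parse_hmmer_tblout(path: str | Path) -> list[AlignmentHit]:
    """Parse HMMER3 tblout: target (col 1), query profile (col 3), full-seq
    E-value (col 5) and score (col 6)."""
    path = Path(path)
    hits: list[AlignmentHit] = []
    n_bad = n_total = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            n_total += 1
            fields = line.split()
            if len(fields) < 6:
                n_bad += 1
                continue
            try:
                hits.append(AlignmentHit(query_id=fields[0], subject_id=fields[2],
                                         evalue=float(fields[4]),
                                         bitscore=float(fields[5])))
            except ValueError:
                n_bad += 1
    _check_malformed(path, n_bad, n_total)
    return hits


# ---------------------------------------------------------------------------
# Lineage / truth / protein tables
# ---------------------------------------------------------------------------

LINEAGE_COLUMNS = ["plasmid_id", *RANKS, "release_date", "length_bp"]


def parse_lineage_table(path: str | Path) -> list[HostLineage]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(LINEAGE_COLUMNS) - set(df.columns)
    if missing:
        raise MalformedFileError(f"{path}: missing columns {sorted(missing)}")
    out: list[HostLineage] = []
    n_bad = 0
    # dict-based row access: 'class' is a keyword, so itertuples would mangle it
    for row in df.to_dict("records"):
        try:
            out.append(HostLineage(
                plasmid_id=row["plasmid_id"],
                ranks=tuple(row[r] for r in RANKS),
                release_date=_dt.date.fromisoformat(row["release_date"]),
                length_bp=int(row["length_bp"])))
        except (ValueError, TypeError):
            n_bad += 1
    _check_malformed(path, n_bad, len(df))
    return out


def write_lineage_table(lineages: Iterable[HostLineage], path: str | Path) -> None:
    rows = [dict(plasmid_id=l.plasmid_id,
                 **dict(zip(RANKS, l.ranks)),
                 release_date=l.release_date.isoformat(),
                 length_bp=l.length_bp)
            for l in lineages]
    pd.DataFrame(rows, columns=LINEAGE_COLUMNS).to_csv(path, sep="\t", index=False)


def parse_truth_table(path: str | Path) -> dict[str, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {row["contig_id"]: tuple(row[r] for r in RANKS if row[r])
            for row in df.to_dict("records")}


def write_truth_table(truth: Mapping[str, tuple[str, ...]],
                      path: str | Path) -> None:
    rows = []
    for cid in sorted(truth):
        lin = truth[cid]
        rows.append(dict(contig_id=cid,
                         **{r: (lin[i] if i < len(lin) else "")
                            for i, r in enumerate(RANKS)}))
    pd.DataFrame(rows, columns=["contig_id", *RANKS]).to_csv(
        path, sep="\t", index=False)


def write_protein_table(contigs: Mapping[str, PlasmidContig],
                        path: str | Path) -> None:
    rows = [dict(contig_id=cid, protein_id=p.protein_id, start=p.start,
                 end=p.end, strand=p.strand)
            for cid in sorted(contigs) for p in contigs[cid].proteins]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def parse_protein_table(path: str | Path) -> dict[str, list[ProteinCall]]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "protein_id": str})
    out: dict[str, list[ProteinCall]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.contig_id, []).append(
            ProteinCall(protein_id=row.protein_id, start=int(row.start),
                        end=int(row.end), strand=int(row.strand)))
    return out


def load_contigs(fasta_path: str | Path,
                 protein_table_path: str | Path) -> dict[str, PlasmidContig]:
    proteins = parse_protein_table(protein_table_path)
    return {cid: PlasmidContig(contig_id=cid, sequence=seq,
                               proteins=proteins.get(cid, []))
            for cid, seq in parse_fasta(fasta_path)}


# ---------------------------------------------------------------------------
# External annotator adapter
# ---------------------------------------------------------------------------

def run_external_annotator(adapter: str, inputs: Mapping[str, str],
                           cfg: PipelineConfig,
                           dry_run: bool = False) -> str | None:
    """Invoke a configured external tool (gene caller, protein/profile/
    nucleotide aligner) through its command template.

    The template for ``adapter`` comes from ``cfg.tool_templates`` and may
    use ``{name}`` placeholders filled from ``inputs``.  With ``dry_run``
    the fully substituted command is logged and returned unexecuted.  The
    test suite never requires this path: synthetic hits substitute for real
    annotator output.
    """
    template = cfg.tool_templates.get(adapter)
    if template is None:
        raise KeyError(
            f"no command template for adapter {adapter!r}; set "
            f"tool_templates[{adapter!r}] in the pipeline configuration")
    try:
        command = template.format(**inputs)
    except KeyError as exc:
        raise KeyError(f"adapter {adapter!r} template needs input {exc}") from None
    logger.info("external command: %s", command)
    if dry_run:
        return command
    result = subprocess.run(shlex.split(command), capture_output=True, text=True)
    if result.returncode != 0:
        raise RuntimeError(
            f"adapter {adapter!r} exited {result.returncode}:\n{result.stderr}")
    return result.stdout
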