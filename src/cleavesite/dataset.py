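"""Sequence and cleavage-annotation handling: windows, negatives, splits.

A cleavage site is annotated as the residue pair (p, p+1) flanking the
scissile bond, with ``p`` 1-based and denoting the P1 residue.  Peptide
windows of even size W = 2k straddle the bond so that window sites k and
k+1 carry protein residues p and p+1; positions that fall outside the
protein are padded with the complement symbol ``X``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AnnotationReferenceError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "X"
WINDOW_SIZES = (16, 18, 20, 22)

_AA_SET = frozenset(AMINO_ACIDS)
_NONSTANDARD = frozenset("BZUOJX")

POSITIVE = 1
NEGATIVE = 0


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its annotated cleavage positions.

    ``sites`` holds 1-based P1 positions; each annotated bond is the pair
    (p, p+1), so every p must satisfy 1 <= p < len(sequence).
    """

    accession: str
    sequence: str
    sites: tuple = ()

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.accession}: empty sequence")
        # X is tolerated inside stored sequences only as the result of an
        # explicit map_nonstandard coercion; it encodes as all-zero features.
        bad = set(self.sequence) - _AA_SET - {PAD}
        if bad:
            raise ValidationError(
                f"{self.accession}: non-standard residue(s) {sorted(bad)}; "
                "only the 20 standard amino-acid letters are accepted "
                "(use map_nonstandard='X' at parse time to coerce)"
            )
        sites = tuple(sorted(set(int(p) for p in self.sites)))
        for p in sites:
            if not 1 <= p < len(self.sequence):
                raise ValidationError(
                    f"{self.accession}: cleavage position {p} out of bounds "
                    f"(needs 1 <= p < {len(self.sequence)} so the pair p, p+1 exists)"
                )
        object.__setattr__(self, "sites", sites)

    def __len__(self):
        return len(self.sequence)

    def noncleavage_bonds(self):
        """1-based positions q with (q, q+1) not annotated as cleaved."""
        taken = set(self.sites)
        return [q for q in range(1, len(self.sequence)) if q not in taken]


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length residue window straddling one candidate bond."""

    residues: str
    w: int
    label: int
    source: tuple  # (accession, p)
    pad_mask: tuple = field(default=())

    def __post_init__(self):
        if len(self.residues) != self.w:
            raise ValidationError("window length does not match declared size")
        if not self.pad_mask:
            object.__setattr__(
                self, "pad_mask", tuple(c == PAD for c in self.residues)
            )


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple
    test: tuple


def read_fasta(source, map_nonstandard=False):
    """Read a multi-record FASTA into ``{accession: sequence}``.

    Non-standard letters (B, Z, U, O, J, X) are rejected unless
    ``map_nonstandard`` is set, in which case they are coerced to ``X``
    (whose features encode as zero, like terminal padding).
    """
    seqs = {}
    for rec in SeqIO.parse(str(source), "fasta"):
        seq = str(rec.seq).upper()
        if map_nonstandard:
            seq = "".join(PAD if c in _NONSTANDARD else c for c in seq)
        seqs[rec.id] = seq
    return seqs


def read_site_table(table_source):
    """Read a cleavage-annotation table (TSV or CSV).

    Columns: ``accession``, ``position`` and optionally ``label``
    (``positive``/``negative`` or 1/0); a missing label column means every
    row is a positive (an annotated cleavage site).
    """
    df = pd.read_csv(table_source, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    if "accession" not in cols or "position" not in cols:
        raise ValidationError(
            "annotation table needs 'accession' and 'position' columns; "
            f"got {list(df.columns)}"
        )
    out = pd.DataFrame(
        {
            "accession": df[cols["accession"]].astype(str),
            "position": df[cols["position"]].astype(int),
        }
    )
    if "label" in cols:
        raw = df[cols["label"]]
        if raw.dtype == object:
            lab = raw.str.strip().str.lower().map(
                {"positive": POSITIVE, "negative": NEGATIVE, "1": POSITIVE, "0": NEGATIVE}
            )
            if lab.isna().any():
                bad = raw[lab.isna()].iloc[0]
                raise ValidationError(f"unrecognised label value {bad!r}")
            out["label"] = lab.astype(int)
        else:
            out["label"] = raw.astype(int)
    else:
        out["label"] = POSITIVE
    return out


def read_annotations(fasta_source, table_source, map_nonstandard=False):
    """Build one ProteinRecord per FASTA accession from a site table.

    Only positive rows contribute cleavage sites; duplicates are dropped
    and sites sorted.  Rows referencing unknown accessions or out-of-bounds
    positions raise immediately with the offending accession/position.
    """
    seqs = read_fasta(fasta_source, map_nonstandard=map_nonstandard)
    table = read_site_table(table_source)
    sites = {acc: set() for acc in seqs}
    for row in table.itertuples(index=False):
        if row.accession not in seqs:
            raise AnnotationReferenceError(
                f"annotation references unknown accession {row.accession!r}"
            )
        L = len(seqs[row.accession])
        if not 1 <= row.position < L:
            raise ValidationError(
                f"{row.accession}: position {row.position} out of bounds for "
                f"length-{L} sequence (pair needs residue {row.position + 1})"
            )
        if row.label == POSITIVE:
            sites[row.accession].add(row.position)
    return [
        ProteinRecord(acc, seq, tuple(sorted(sites[acc])))
        for acc, seq in seqs.items()
    ]


def extract_window(record, p, w):
    """Extract the size-``w`` window whose central bond is (p, p+1).

    With k = w/2 the window covers protein positions p-k+1 .. p+k, so
    window sites k and k+1 (1-based) hold residues p and p+1; positions
    outside [1, len] are padded with ``X``.
    """
    if w not in WINDOW_SIZES:
        raise ValidationError(f"window size must be one of {WINDOW_SIZES}, got {w}")
    L = len(record.sequence)
    if not 1 <= p < L:
        raise ValidationError(f"{record.accession}: p={p} out of range for length {L}")
    k = w // 2
    chars = []
    for s in range(1, w + 1):
        pos = p - k + s
        chars.append(record.sequence[pos - 1] if 1 <= pos <= L else PAD)
    label = POSITIVE if p in record.sites else NEGATIVE
    return PeptideWindow("".join(chars), w, label, (record.accession, p))


def positive_windows(records, w):
    """All annotated-site windows across a protein set, labelled positive."""
    return [extract_window(r, p, w) for r in records for p in r.sites]


def sample_negatives(records, w, ratio, rng, n_positives=None):
    """Sample negative windows centred on non-cleavage bonds.

    Candidate bonds (q, q+1) with q not annotated are pooled across the
    whole protein set and sampled uniformly without replacement, targeting
    ``ratio`` negatives per positive globally.  If the pool is smaller than
    the request, everything available is returned with a warning.
    """
    if isinstance(records, ProteinRecord):
        records = [records]
    if ratio < 1:
        raise ValidationError("negative:positive ratio must be >= 1")
    pool = [(r, q) for r in records for q in r.noncleavage_bonds()]
    if not pool:
        raise ValidationError("no non-cleavage bonds available")
    if n_positives is None:
        n_positives = sum(len(r.sites) for r in records)
    want = ratio * n_positives
    if want > len(pool):
        warnings.warn(
            f"requested {want} negatives but only {len(pool)} non-cleavage "
            "bonds exist; returning all of them"
        )
        idx = np.arange(len(pool))
    else:
        idx = rng.choice(len(pool), size=want, replace=False)
    return [extract_window(pool[i][0], pool[i][1], w) for i in sorted(idx)]


def windows_from_table(records, table, w):
    """Materialise labelled windows for every row of a sample table."""
    by_acc = {r.accession: r for r in records}
    out = []
    for row in table.itertuples(index=False):
        rec = by_acc.get(row.accession)
        if rec is None:
            raise AnnotationReferenceError(
                f"table references unknown accession {row.accession!r}"
            )
        win = extract_window(rec, row.position, w)
        if win.label != row.label:
            win = PeptideWindow(win.residues, w, int(row.label), win.source)
        out.append(win)
    return out


def split_train_test(records, test_fraction, rng):
    """Protein-level train/test partition, reproducible under the rng seed."""
    records = list(records)
    if len(records) < 2:
        raise ValidationError("need at least 2 proteins to split")
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must lie in (0, 1)")
    n = len(records)
    n_test = int(round(test_fraction * n))
    n_test = max(1, min(n - 1, n_test))
    order = rng.permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = tuple(records[i] for i in range(n) if i not in test_idx)
    test = tuple(records[i] for i in range(n) if i in test_idx)
    return DatasetSplit(train=train, test=test)


def windows_to_frame(windows):
    """Tabular view of a window list (TSV-friendly)."""
    return pd.DataFrame(
        {
            "accession": [w.source[0] for w in windows],
            "position": [w.source[1] for w in windows],
            "label": [w.label for w in windows],
            "window": [w.residues for w in windows],
        }
    )
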