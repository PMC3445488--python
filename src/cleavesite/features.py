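"""Per-residue feature encoding for peptide windows.

Each residue of a window contributes 32 features in a fixed order:

==========  =====  ==========================================================
family      width  content
==========  =====  ==========================================================
pssm          20   PSI-BLAST conservation scores, column order ARNDCQEGHILKMFPSTWYV
disorder       1   intrinsic-disorder score in [0, 1]
aafactor       5   Atchley factors: polarity, secondary-structure propensity,
                   molecular volume, codon diversity, electrostatic charge
sa             2   solvent accessibility one-hot: buried=10, exposed=01
ss             3   secondary structure one-hot: helix=100, strand=010, other=001
freq           1   training-positive occurrence frequency of the residue's
                   symbol at its window site
==========  =====  ==========================================================

Padding residues (``X``) encode as 32 zeros in every family.  Columns are
named ``AA{site}_{family}_{k}`` with 1-based site and within-family index,
e.g. ``AA11_pssm_20`` is the conservation score against valine at site 11.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import AMINO_ACIDS, PAD, PeptideWindow
from .errors import FormatError, ValidationError

# PSI-BLAST matrix column order (differs from the alphabetical window order)
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

SS_CLASSES = ("H", "E", "O")  # helix, strand, other
SA_CLASSES = ("b", "e")       # buried, exposed

FAMILY_WIDTHS = {
    "pssm": 20,
    "disorder": 1,
    "aafactor": 5,
    "sa": 2,
    "ss": 3,
    "freq": 1,
}
FAMILY_ORDER = ("pssm", "disorder", "aafactor", "sa", "ss", "freq")
FEATURES_PER_RESIDUE = sum(FAMILY_WIDTHS.values())  # 32

FREQ_SYMBOLS = AMINO_ACIDS + PAD  # 21 symbols, X last

# Atchley et al. factor solution scores for the 20 amino acids, in the order
# (polarity, secondary structure, molecular volume, codon diversity, charge).
ATCHLEY_FACTORS = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
}

_NAME_RE = re.compile(r"^AA(\d+)_(pssm|disorder|aafactor|sa|ss|freq)_(\d+)$")


def format_feature_name(site, family, k):
    return f"AA{site}_{family}_{k}"


def parse_feature_name(name):
    """Invert the ``AA{site}_{family}_{k}`` grammar."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValidationError(f"feature name {name!r} does not parse")
    site, family, k = int(m.group(1)), m.group(2), int(m.group(3))
    if not 1 <= k <= FAMILY_WIDTHS[family]:
        raise ValidationError(f"feature name {name!r}: index {k} out of range")
    return site, family, k


def feature_names(w):
    """Canonical column names for a size-``w`` window (w x 32 of them)."""
    names = []
    for site in range(1, w + 1):
        for family in FAMILY_ORDER:
            for k in range(1, FAMILY_WIDTHS[family] + 1):
                names.append(format_feature_name(site, family, k))
    return names


# ---------------------------------------------------------------------------
# per-residue annotation profiles and their file dialects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSSMProfile:
    """Length x 20 conservation scores, PSI-BLAST column order."""

    scores: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.scores, dtype=float)
        if a.ndim != 2 or a.shape[1] != 20:
            raise ValidationError("PSSM profile must be length x 20")
        object.__setattr__(self, "scores", a)

    def __len__(self):
        return len(self.scores)


@dataclass(frozen=True)
class StructureProfile:
    """Per-residue secondary-structure (H/E/O) and accessibility (b/e) strings."""

    ss: str
    sa: str

    def __post_init__(self):
        if len(self.ss) != len(self.sa):
            raise ValidationError("ss and sa strings differ in length")
        if set(self.ss) - set(SS_CLASSES):
            raise ValidationError("secondary structure string must use H/E/O")
        if set(self.sa) - set(SA_CLASSES):
            raise ValidationError("accessibility string must use b/e")

    def __len__(self):
        return len(self.ss)


def load_pssm(source, sequence=None):
    """Parse a PSI-BLAST ASCII scoring matrix (first 20 score columns).

    The reader locates the header row listing the 20 amino-acid columns and
    then consumes one row per residue: index, residue letter, >=20 numbers.
    If ``sequence`` is given the profile length is checked against it.
    """
    lines = Path(source).read_text().splitlines()
    header_at = None
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and "".join(toks[:20]) == PSSM_ALPHABET:
            header_at = i
            break
    if header_at is None:
        raise FormatError(f"{source}: no PSI-BLAST column header found")
    rows = []
    for ln, line in enumerate(lines[header_at + 1:], start=header_at + 2):
        toks = line.split()
        if not toks:
            break
        if not toks[0].isdigit():
            break
        if len(toks) < 22:
            raise FormatError(
                f"{source}:{ln}: expected index, residue and 20 scores, "
                f"got {len(toks)} fields"
            )
        try:
            rows.append([float(t) for t in toks[2:22]])
        except ValueError as e:
            raise FormatError(f"{source}:{ln}: non-numeric score ({e})") from None
    if not rows:
        raise FormatError(f"{source}: no matrix rows found")
    profile = PSSMProfile(np.array(rows))
    if sequence is not None and len(profile) != len(sequence):
        raise FormatError(
            f"{source}: matrix has {len(profile)} rows but sequence "
            f"has {len(sequence)} residues"
        )
    return profile


def write_pssm(profile, sequence, dest):
    """Write a profile in the ASCII dialect :func:`load_pssm` reads."""
    lines = ["", "Last position-specific scoring matrix computed",
             "            " + "   ".join(PSSM_ALPHABET)]
    for i, (aa, row) in enumerate(zip(sequence, profile.scores), start=1):
        cells = " ".join(f"{v:5g}" for v in row)
        lines.append(f"{i:5d} {aa}  {cells}  {cells}")
    Path(dest).write_text("\n".join(lines) + "\n")


def load_disorder(source, sequence=None):
    """Read a two-column (position, score) TSV of per-residue disorder."""
    df = pd.read_csv(source, sep="\t", header=None, names=["position", "score"])
    scores = np.full(int(df["position"].max()), np.nan)
    scores[df["position"].to_numpy(int) - 1] = df["score"].to_numpy(float)
    if np.isnan(scores).any():
        raise FormatError(f"{source}: missing positions in disorder table")
    if ((scores < 0) | (scores > 1)).any():
        raise FormatError(f"{source}: disorder scores must lie in [0, 1]")
    if sequence is not None and len(scores) != len(sequence):
        raise FormatError(f"{source}: length mismatch with sequence")
    return scores


def write_disorder(scores, dest):
    pd.DataFrame({"position": np.arange(1, len(scores) + 1), "score": scores}) \
        .to_csv(dest, sep="\t", header=False, index=False)


def load_structure(ss_source, sa_source):
    """Read FASTA-like single-record class-string files (H/E/O and b/e)."""
    def _read(path):
        lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
        if not lines or not lines[0].startswith(">"):
            raise FormatError(f"{path}: expected a '>' header line")
        return "".join(lines[1:])

    return StructureProfile(ss=_read(ss_source), sa=_read(sa_source))


def write_structure(profile, accession, ss_dest, sa_dest):
    Path(ss_dest).write_text(f">{accession}\n{profile.ss}\n")
    Path(sa_dest).write_text(f">{accession}\n{profile.sa}\n")


@dataclass
class AnnotationProviders:
    """Per-protein profile lookups backing the pssm/disorder/sa/ss families."""

    pssm: dict
    disorder: dict
    structure: dict

    def _get(self, table, accession, what):
        try:
            return table[accession]
        except KeyError:
            raise KeyError(
                f"no {what} profile available for accession {accession!r}"
            ) from None

    def pssm_for(self, accession):
        return self._get(self.pssm, accession, "PSSM")

    def disorder_for(self, accession):
        return self._get(self.disorder, accession, "disorder")

    def structure_for(self, accession):
        return self._get(self.structure, accession, "structure")

    def validate(self, records):
        for r in records:
            for prof in (self.pssm_for(r.accession),
                         self.disorder_for(r.accession),
                         self.structure_for(r.accession)):
                if len(prof) != len(r.sequence):
                    raise ValidationError(
                        f"{r.accession}: profile length {len(prof)} != "
                        f"sequence length {len(r.sequence)}"
                    )


# ---------------------------------------------------------------------------
# frequency table and encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyTable:
    """W x 21 empirical symbol frequencies at each window site of positives."""

    table: np.ndarray  # rows: window sites, cols: FREQ_SYMBOLS

    def __post_init__(self):
        a = np.asarray(self.table, dtype=float)
        if a.ndim != 2 or a.shape[1] != len(FREQ_SYMBOLS):
            raise ValidationError("frequency table must be W x 21")
        if (a < 0).any() or not np.allclose(a.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("frequency table rows must be distributions")
        object.__setattr__(self, "table", a)

    @property
    def w(self):
        return self.table.shape[0]

    def lookup(self, site, symbol):
        return float(self.table[site - 1, FREQ_SYMBOLS.index(symbol)])

    def to_frame(self):
        return pd.DataFrame(
            self.table,
            index=pd.RangeIndex(1, self.w + 1, name="site"),
            columns=list(FREQ_SYMBOLS),
        )


def build_frequency_table(positives):
    """Empirical per-site symbol distribution over positive windows."""
    positives = list(positives)
    if not positives:
        raise ValidationError("cannot build a frequency table from zero windows")
    w = positives[0].w
    if any(win.w != w for win in positives):
        raise ValidationError("all windows must share one window size")
    if any(win.label != 1 for win in positives):
        raise ValidationError("frequency table is defined over positive windows")
    counts = np.zeros((w, len(FREQ_SYMBOLS)))
    idx = {c: j for j, c in enumerate(FREQ_SYMBOLS)}
    for win in positives:
        for s, c in enumerate(win.residues):
            counts[s, idx[c]] += 1
    return FrequencyTable(counts / counts.sum(axis=1, keepdims=True))


def encode_residue(symbol, site, pssm_row, disorder_value, structure, freq_table):
    """Encode one residue as its 32-feature vector.

    ``structure`` is an (ss_class, sa_class) pair from H/E/O and b/e.
    The padding symbol ``X`` yields 32 zeros regardless of the other inputs.
    """
    if symbol == PAD:
        return np.zeros(FEATURES_PER_RESIDUE)
    if symbol not in ATCHLEY_FACTORS:
        raise ValidationError(f"unknown residue symbol {symbol!r}")
    ss, sa = structure
    vec = np.empty(FEATURES_PER_RESIDUE)
    vec[0:20] = np.asarray(pssm_row, dtype=float)
    vec[20] = float(disorder_value)
    vec[21:26] = ATCHLEY_FACTORS[symbol]
    vec[26:28] = [1.0 if sa == c else 0.0 for c in SA_CLASSES]
    vec[28:31] = [1.0 if ss == c else 0.0 for c in SS_CLASSES]
    vec[31] = freq_table.lookup(site, symbol)
    return vec


@dataclass
class FeatureMatrix:
    """samples x (W x 32) numeric matrix with canonical column names."""

    values: np.ndarray
    columns: list
    meta: pd.DataFrame  # accession, position, label per row

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.columns):
            raise ValidationError("column-name count does not match matrix width")
        if len(self.meta) != self.values.shape[0]:
            raise ValidationError("metadata row count does not match matrix")
        self._col_index = {c: j for j, c in enumerate(self.columns)}

    @property
    def labels(self):
        return self.meta["label"].to_numpy(int)

    @property
    def w(self):
        return len(self.columns) // FEATURES_PER_RESIDUE

    def select(self, names):
        """Column-subset view in the requested order."""
        try:
            idx = [self._col_index[n] for n in names]
        except KeyError as e:
            raise ValidationError(f"unknown feature column {e.args[0]!r}") from None
        return self.values[:, idx]

    def to_frame(self):
        df = pd.DataFrame(self.values, columns=self.columns)
        return pd.concat([self.meta.reset_index(drop=True), df], axis=1)

    @classmethod
    def from_frame(cls, df):
        meta_cols = ["accession", "position", "label"]
        cols = [c for c in df.columns if c not in meta_cols]
        return cls(df[cols].to_numpy(float), cols, df[meta_cols].copy())


def encode_windows(windows, providers, freq_table):
    """Encode a window list into a :class:`FeatureMatrix`.

    Providers must cover every source protein; a missing profile raises a
    lookup error naming the accession.  Rows keep the window order; columns
    run site 1..W with the 32-feature family order within each site.
    """
    windows = list(windows)
    if not windows:
        raise ValidationError("no windows to encode")
    w = windows[0].w
    if freq_table.w != w:
        raise ValidationError("frequency table window size does not match windows")
    names = feature_names(w)
    k = w // 2
    X = np.zeros((len(windows), len(names)))
    for i, win in enumerate(windows):
        acc, p = win.source
        pssm = providers.pssm_for(acc)
        dis = providers.disorder_for(acc)
        struct = providers.structure_for(acc)
        for s in range(1, w + 1):
            symbol = win.residues[s - 1]
            if symbol == PAD:
                continue
            pos = p - k + s  # 1-based protein position at window site s
            vec = encode_residue(
                symbol,
                s,
                pssm.scores[pos - 1],
                dis[pos - 1],
                (struct.ss[pos - 1], struct.sa[pos - 1]),
                freq_table,
            )
            X[i, (s - 1) * FEATURES_PER_RESIDUE: s * FEATURES_PER_RESIDUE] = vec
    meta = pd.DataFrame(
        {
            "accession": [win.source[0] for win in windows],
            "position": [win.source[1] for win in windows],
            "label": [win.label for win in windows],
        }
    )
    return FeatureMatrix(X, names, meta)


def synthetic_providers(records, motif_spec, rng):
    """Deterministic-under-seed stand-in profiles for every record.

    PSSM rows are small-integer noise with the residue's own column boosted,
    so profile argmax tracks sequence identity; disorder is uniform noise in
    [0, 1]; secondary-structure and accessibility classes are drawn from the
    motif spec's background distributions, with strand enrichment in the
    two residues flanking each annotated bond and buried enrichment at the
    bond itself.
    """
    pssm, disorder, structure = {}, {}, {}
    col_of = {aa: j for j, aa in enumerate(PSSM_ALPHABET)}
    ss_bg = np.array(motif_spec.ss_background)
    for rec in records:
        L = len(rec.sequence)
        scores = np.round(rng.normal(0.0, motif_spec.pssm_noise_sd, (L, 20)))
        for i, aa in enumerate(rec.sequence):
            if aa in col_of:
                scores[i, col_of[aa]] += motif_spec.pssm_self_boost
        pssm[rec.accession] = PSSMProfile(scores)
        disorder[rec.accession] = rng.uniform(0.0, 1.0, L)
        ss = rng.choice(len(SS_CLASSES), size=L, p=ss_bg)
        buried = rng.uniform(size=L) < motif_spec.sa_background_buried
        for p in rec.sites:
            near = [q for q in (p - 1, p, p + 1, p + 2) if 1 <= q <= L]
            strand = rng.uniform(size=len(near)) < motif_spec.strand_prob_near_bond
            for q, hit in zip(near, strand):
                if hit:
                    ss[q - 1] = SS_CLASSES.index("E")
            for q in (p, p + 1):
                if 1 <= q <= L:
                    buried[q - 1] = rng.uniform() < motif_spec.buried_prob_at_bond
        structure[rec.accession] = StructureProfile(
            ss="".join(SS_CLASSES[i] for i in ss),
            sa="".join("b" if b else "e" for b in buried),
        )
    return AnnotationProviders(pssm=pssm, disorder=disorder, structure=structure)
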