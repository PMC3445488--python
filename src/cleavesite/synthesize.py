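"""Seed-reproducible synthetic benchmark data with a planted cleavage motif.

The generator emulates the study conditions of a protease cleavage-site
corpus: proteins drawn from a background amino-acid distribution, with
annotated scissile bonds whose flanking residues follow site-specific
emission distributions (by default arginine/aspartate at the P1 site and
serine/alanine/glycine at P1', i.e. window sites 11 and 12 of a size-22
window), plus strand and buried-class enrichment near the bond in the
synthetic structure profiles.  ``strength`` interpolates between pure
background (0, no signal) and the pure motif emissions (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset as ds
from .dataset import AMINO_ACIDS, ProteinRecord
from .errors import GenerationError, ValidationError
from .features import synthetic_providers

REFERENCE_W = 22  # motif emission sites are indexed in this window frame


def _as_dist(d):
    syms = list(d)
    p = np.array([d[s] for s in syms], dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"probabilities must be a distribution, got {d}")
    return syms, p


@dataclass(frozen=True)
class MotifSpec:
    """Planted-signal description for positive windows.

    ``emissions`` maps window sites (size-22 frame, bond between 11 and 12)
    to within-motif symbol distributions; the actual emission at a planted
    site is ``strength * motif + (1 - strength) * background``.
    """

    emissions: dict = field(default_factory=lambda: {
        11: {"R": 0.5, "D": 0.5},
        12: {"S": 0.4, "A": 0.3, "G": 0.3},
    })
    background: dict = field(default_factory=lambda: {
        aa: 1.0 / 20 for aa in AMINO_ACIDS
    })
    strength: float = 0.85
    ss_background: tuple = (0.35, 0.20, 0.45)   # H, E, O
    sa_background_buried: float = 0.5
    strand_prob_near_bond: float = 0.5
    buried_prob_at_bond: float = 0.8
    pssm_self_boost: float = 4.0
    pssm_noise_sd: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.strength <= 1.0:
            raise ValidationError("strength must lie in [0, 1]")
        _as_dist(self.background)
        for site, dist in self.emissions.items():
            _as_dist(dist)
        if abs(sum(self.ss_background) - 1.0) > 1e-9:
            raise ValidationError("ss_background must sum to 1")

    def site_distribution(self, site):
        """Effective emission distribution at a window site (over 20 AAs)."""
        bg_syms, bg_p = _as_dist(self.background)
        probs = {s: (1 - self.strength) * p for s, p in zip(bg_syms, bg_p)}
        if site in self.emissions:
            for s, p in self.emissions[site].items():
                probs[s] = probs.get(s, 0.0) + self.strength * p
        else:
            probs = dict(zip(bg_syms, bg_p))
        return probs


def _draw(rng, dist):
    syms, p = _as_dist(dist)
    return syms[rng.choice(len(syms), p=p)]


def _generate_record(accession, length, n_sites, motif, rng):
    if n_sites > length - 1:
        raise GenerationError(
            f"{accession}: cannot place {n_sites} sites in a length-{length} "
            "protein (needs n_sites <= length - 1)"
        )
    bg_syms, bg_p = _as_dist(motif.background)
    seq = [bg_syms[i] for i in rng.choice(len(bg_syms), size=length, p=bg_p)]
    sites = sorted(rng.choice(np.arange(1, length), size=n_sites,
                              replace=False).tolist())
    k = REFERENCE_W // 2
    for p in sites:
        for site, motif_dist in motif.emissions.items():
            pos = p - k + site
            if 1 <= pos <= length and rng.uniform() < motif.strength:
                seq[pos - 1] = _draw(rng, motif_dist)
    return ProteinRecord(accession, "".join(seq), tuple(sites))


def generate_dataset(n_proteins, length_range, sites_per_protein, motif=None,
                     rng=None, prefix="SYN"):
    """Generate proteins, their cleavage annotations and provider profiles.

    ``sites_per_protein`` is a constant or one count per protein.  Returns
    ``(records, annotation_table, providers)`` where the table has the
    accession/position/label columns the real readers consume.
    """
    motif = motif or MotifSpec()
    rng = rng if rng is not None else np.random.default_rng(0)
    if n_proteins < 1 or length_range[0] < REFERENCE_W:
        raise GenerationError(
            "need n_proteins >= 1 and min length >= the largest window (22)"
        )
    if np.isscalar(sites_per_protein):
        counts = [int(sites_per_protein)] * n_proteins
    else:
        counts = [int(c) for c in sites_per_protein]
        if len(counts) != n_proteins:
            raise GenerationError("one site count per protein required")
    lengths = rng.integers(length_range[0], length_range[1] + 1,
                           size=n_proteins)
    records = [
        _generate_record(f"{prefix}{i + 1:05d}", int(lengths[i]), counts[i],
                         motif, rng)
        for i in range(n_proteins)
    ]
    table = pd.DataFrame(
        [(r.accession, p, ds.POSITIVE) for r in records for p in r.sites],
        columns=["accession", "position", "label"],
    )
    providers = synthetic_providers(records, motif, rng)
    return records, table, providers


@dataclass
class ScenarioBundle:
    """One fully materialised benchmark: records, windows, providers."""

    train_records: list
    test_records: list
    train_windows: list   # positives then negatives
    test_windows: list
    providers: object
    motif: MotifSpec
    w: int

    def sample_table(self, split):
        windows = self.train_windows if split == "train" else self.test_windows
        return ds.windows_to_frame(windows)[["accession", "position", "label"]]


def _allocate_sites(n_proteins, total_sites, rng):
    """Each protein gets >= 1 site; the surplus is spread at random."""
    if total_sites < n_proteins:
        raise GenerationError("need at least one site per protein")
    counts = np.ones(n_proteins, dtype=int)
    extra = rng.choice(n_proteins, size=total_sites - n_proteins, replace=True)
    np.add.at(counts, extra, 1)
    return counts.tolist()


def default_scenario(seed, w=22, neg_ratio=3, motif=None,
                     n_train=371, n_test=88, train_sites=578, test_sites=134,
                     length_range=(60, 300)):
    """The benchmark at full corpus scale: 459 proteins carrying 712
    annotated bonds, split 371/88 at protein level with 578/134 positive
    windows, and 3:1 randomly sampled negatives (1734/402).

    Everything — sequences, annotations, provider profiles, negative
    sampling — derives from one integer seed.
    """
    rng = np.random.default_rng(seed)
    motif = motif or MotifSpec()
    train_counts = _allocate_sites(n_train, train_sites, rng)
    test_counts = _allocate_sites(n_test, test_sites, rng)

    def _build(n, counts, prefix):
        lengths = rng.integers(length_range[0], length_range[1] + 1, size=n)
        return [
            _generate_record(f"{prefix}{i + 1:05d}", int(lengths[i]),
                             counts[i], motif, rng)
            for i in range(n)
        ]

    train_records = _build(n_train, train_counts, "TRN")
    test_records = _build(n_test, test_counts, "TST")
    providers = synthetic_providers(train_records + test_records, motif, rng)

    train_pos = ds.positive_windows(train_records, w)
    train_neg = ds.sample_negatives(train_records, w, neg_ratio, rng)
    test_pos = ds.positive_windows(test_records, w)
    test_neg = ds.sample_negatives(test_records, w, neg_ratio, rng)
    return ScenarioBundle(
        train_records=train_records,
        test_records=test_records,
        train_windows=train_pos + train_neg,
        test_windows=test_pos + test_neg,
        providers=providers,
        motif=motif,
        w=w,
    )


def write_bundle(bundle, outdir):
    """Write a scenario to disk in the dialects the real pipeline reads:
    FASTA, S1-shaped sample tables, and per-protein provider files."""
    from .features import write_disorder, write_pssm, write_structure

    out = Path(outdir)
    for sub in ("pssm", "disorder", "struct"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    records = list(bundle.train_records) + list(bundle.test_records)
    with open(out / "proteins.fasta", "w") as fh:
        for r in records:
            fh.write(f">{r.accession}\n{r.sequence}\n")
    for split in ("train", "test"):
        tab = bundle.sample_table(split)
        tab = tab.assign(label=tab["label"].map({1: "positive", 0: "negative"}))
        tab.to_csv(out / f"{split}_samples.tsv", sep="\t", index=False)
    for r in records:
        acc = r.accession
        write_pssm(bundle.providers.pssm_for(acc), r.sequence,
                   out / "pssm" / f"{acc}.pssm")
        write_disorder(bundle.providers.disorder_for(acc),
                       out / "disorder" / f"{acc}.tsv")
        write_structure(bundle.providers.structure_for(acc), acc,
                        out / "struct" / f"{acc}.ss",
                        out / "struct" / f"{acc}.sa")
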