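"""Synthetic reference bundle and small-RNA library simulator.

Emulates the study design the pipeline is built for: two adapter-ligated
small-RNA libraries (young leaves vs. glandular trichomes) of fixed-length
49-nt reads whose inserts are dominated by 24-nt then 21-nt species, over a
transcriptome that carries planted ground truth:

* conserved miRNA families (reference matures, some with 1-mismatch variant
  tags and with known 8-fold tissue differences),
* novel miRNA hairpin precursors embedded in transcripts (stem folding below
  -18 kcal/mol, mature on a known arm),
* miRNA target sites designed to pass all six target rules or to violate one
  designated rule each,
* ncRNA contaminant fragments (rRNA/tRNA/snRNA/snoRNA) and read-level
  artifacts (low-quality, adapter issues, poly(A), short inserts).

Expression truth is drawn log-normal per tag with condition multipliers;
per-library counts are one multinomial draw over the truth profile, so
counts sum exactly to the configured read number.  Reads carry per-position
Gaussian Phred qualities and quality-driven substitution errors.  Everything
is deterministic under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._seq import normalize_rna, revcomp
from . import rna_structure, targets
from .conserved import align_ungapped
from .io import FastaRecord, write_fasta
from .preprocess import CleanConfig, find_adapter3

LIBRARIES = ("leaves", "trichomes")
ARTIFACT_CLASSES = ("low_quality", "adapter5", "no_adapter3", "adapter_dimer", "polya", "short")

_DNA = "ACGT"


@dataclass
class SimulationConfig:
    """Study-condition parameters of the simulator."""

    seed: int = 1
    n_reads: int = 100_000  # per library
    read_length: int = 49
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    phred_offset: int = 33
    qual_mean: float = 36.0
    qual_sd: float = 3.0
    # insert length profile for background tags: 24 nt dominates, then 21, then 23
    insert_length_weights: dict[int, float] = field(
        default_factory=lambda: {
            18: 0.010, 19: 0.010, 20: 0.030, 21: 0.180, 22: 0.040, 23: 0.070,
            24: 0.550, 25: 0.040, 26: 0.020, 27: 0.020, 28: 0.010, 29: 0.010, 30: 0.010,
        }
    )
    # read-level artifact fractions (of n_reads)
    frac_low_quality: float = 0.010
    frac_adapter5: float = 0.0020
    frac_no_adapter3: float = 0.0015
    frac_adapter_dimer: float = 0.0002
    frac_polya: float = 0.0004
    frac_short: float = 0.0008
    # clean-read composition fractions (of the non-artifact mass)
    frac_rrna: float = 0.030
    frac_trna: float = 0.012
    frac_snrna: float = 0.0015
    frac_snorna: float = 0.0008
    frac_conserved: float = 0.060
    frac_novel: float = 0.006
    # reference-bundle sizes
    n_transcripts: int = 60
    transcript_len_range: tuple[int, int] = (400, 1500)
    n_conserved_families: int = 50
    n_decoy_families: int = 10
    n_variant_families: int = 12  # families that also get a 1-mismatch member tag
    n_novel: int = 10
    n_de_families: int = 8
    de_log2fc: float = 3.0  # 8-fold planted tissue difference
    n_background_mapped: int = 250
    n_background_random: int = 50

    def artifact_fractions(self) -> dict[str, float]:
        return {
            "low_quality": self.frac_low_quality,
            "adapter5": self.frac_adapter5,
            "no_adapter3": self.frac_no_adapter3,
            "adapter_dimer": self.frac_adapter_dimer,
            "polya": self.frac_polya,
            "short": self.frac_short,
        }

    def validate(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not self.adapter3 or len(self.adapter3) >= self.read_length:
            raise ValueError("3' adapter must be nonempty and shorter than the read length")
        if any(w < 0 for w in self.insert_length_weights.values()) or not self.insert_length_weights:
            raise ValueError("insert length weights must be nonnegative and nonempty")
        fracs = list(self.artifact_fractions().values()) + [
            self.frac_rrna, self.frac_trna, self.frac_snrna, self.frac_snorna,
            self.frac_conserved, self.frac_novel,
        ]
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be nonnegative")
        if sum(self.artifact_fractions().values()) > 1:
            raise ValueError("artifact fractions must sum to at most 1")
        if self.n_de_families > self.n_conserved_families:
            raise ValueError("more DE families than conserved families")

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = asdict(self)
        d["transcript_len_range"] = list(self.transcript_len_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "transcript_len_range" in d:
            d["transcript_len_range"] = tuple(d["transcript_len_range"])
        if "insert_length_weights" in d:
            d["insert_length_weights"] = {int(k): float(v) for k, v in d["insert_length_weights"].items()}
        return cls(**d)


@dataclass(frozen=True)
class PlantedPrecursor:
    precursor_id: str
    transcript_id: str
    start: int  # 0-based half-open on the transcript
    end: int
    arm: str  # '5p' | '3p'
    mature: str  # RNA alphabet
    precursor_seq: str  # RNA alphabet
    energy: float  # kcal/mol of the isolated precursor fold


@dataclass(frozen=True)
class PlantedSite:
    mirna_id: str
    mirna: str  # RNA
    transcript_id: str
    start: int
    end: int
    outcome: str  # 'pass' or 'fail-rule-<n>'
    expect_accept: bool
    expect_fail_rule: int | None


@dataclass
class Truth:
    tags: pd.DataFrame  # tag (RNA), kind, family, weight_leaves, weight_trichomes
    planted_precursors: list[PlantedPrecursor]
    planted_sites: list[PlantedSite]
    de_families: dict[str, float]  # family -> planted log2 fold change (trichomes/leaves)

    def check(self, transcriptome: dict[str, str]) -> None:
        for p in self.planted_precursors:
            t = transcriptome[p.transcript_id]
            if not (0 <= p.start < p.end <= len(t)):
                raise AssertionError("planted precursor outside its transcript")
            if p.mature not in p.precursor_seq:
                raise AssertionError("planted mature not a substring of its precursor")
        for fc in self.de_families.values():
            if not np.isfinite(fc):
                raise AssertionError("non-finite planted fold change")


@dataclass
class ReferenceBundle:
    transcriptome: dict[str, str]  # DNA alphabet
    mirna_mature: list[FastaRecord]  # RNA alphabet, miRBase-style ids
    mirna_precursor: list[FastaRecord]
    ncrna: dict[str, list[FastaRecord]]  # category -> records (DNA)
    truth: Truth
    annotation_map: dict[str, set[str]]  # transcript id -> term ids

    def write(self, out_dir: str | os.PathLike) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "transcriptome.fa", [(t, s) for t, s in self.transcriptome.items()])
        write_fasta(out / "mirna_mature.fa", [(r.id, r.seq) for r in self.mirna_mature])
        write_fasta(out / "mirna_precursor.fa", [(r.id, r.seq) for r in self.mirna_precursor])
        nc = []
        for cat in sorted(self.ncrna):
            nc.extend((f"{r.id} {cat}", r.seq) for r in self.ncrna[cat])
        write_fasta(out / "ncrna.fa", nc)
        ann = pd.DataFrame(
            [(t, term) for t, terms in sorted(self.annotation_map.items()) for term in sorted(terms)],
            columns=["transcript_id", "term"],
        )
        ann.to_csv(out / "annotation.tsv", sep="\t", index=False)


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = _DNA) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _mm_site_base(mirna_base: str) -> str:
    # pairing a base with itself is never WC nor wobble
    return mirna_base


def _wobble_site_base(mirna_base: str) -> str:
    if mirna_base == "G":
        return "U"
    if mirna_base == "U":
        return "G"
    raise ValueError("wobble requires a G or U miRNA base")


def _design_site(mirna: str, mm_positions: tuple[int, ...], gu_positions: tuple[int, ...]) -> str:
    """Target site (RNA, 5'->3') with designed states at 1-based miRNA positions."""
    site = list(revcomp(mirna))
    L = len(mirna)
    for pos in mm_positions:
        site[L - pos] = _mm_site_base(mirna[pos - 1])
    for pos in gu_positions:
        site[L - pos] = _wobble_site_base(mirna[pos - 1])
    return "".join(site)


def _verify_site(mirna: str, site: str) -> targets.TargetHit:
    alns = targets.align_duplex("m", mirna, "t", site, score_cutoff=float("inf"))
    aln = next(a for a in alns if a.start == 0 and a.end == len(site))
    return targets.score_duplex(aln, site)


def _build_precursor(
    rng: np.random.Generator, mature: str, arm: str, ext: int = 20, n_arm_mutations: int = 2
) -> tuple[str, float]:
    """Hairpin precursor (RNA) carrying ``mature`` on the requested arm.

    The stem is the mature extended by ``ext`` random bases, closed by an
    8-nt loop and the mutated reverse complement; mutations sit opposite the
    extension so the mature stays fully paired.  Retries until the isolated
    fold is at or below -18 kcal/mol (a full-length stem virtually always is).
    """
    for _ in range(20):
        extension = _rand_seq(rng, ext, "ACGU")
        if arm == "5p":
            stem5 = mature + extension
            mutable = range(0, ext)  # arm3 positions opposite the extension
        else:
            stem5 = extension + revcomp(mature)
            mutable = range(len(stem5) - ext, len(stem5))
        arm3 = list(revcomp(stem5))
        for pos in rng.choice(list(mutable), size=min(n_arm_mutations, ext), replace=False):
            old = arm3[pos]
            arm3[pos] = "ACGU"[(("ACGU".index(old)) + int(rng.integers(1, 4))) % 4]
        loop = "GAAA" + _rand_seq(rng, 4, "AC")
        precursor = stem5 + loop + "".join(arm3)
        result = rna_structure.fold(precursor)
        if result.energy > -18.0:
            continue
        # the isolated precursor must itself survive the hairpin criteria
        from .novel import CandidateWindow, evaluate_hairpin

        off = precursor.find(mature)
        cand = evaluate_hairpin(
            CandidateWindow(
                transcript_id="synthetic",
                start=0,
                end=len(precursor),
                tag=mature,
                tag_start=off,
                tag_end=off + len(mature),
                seq=precursor,
            ),
            support=10,
        )
        if cand.accepted and cand.arm == arm:
            return precursor, result.energy
    raise RuntimeError("could not build a stable planted precursor")


def _design_fail6_mature(rng: np.random.Generator) -> tuple[str, str]:
    """A mature + site failing only the energy-ratio rule.

    AU-rich 5' half, G/C island in the 3' half; mismatches placed in the
    island until rules 1-5 pass while the energy ratio drops below 75%.
    """
    for _ in range(200):
        mature = _rand_seq(rng, 13, "AU") + _rand_seq(rng, 8, "GC")
        for mm in ((15, 16, 18), (14, 15, 17), (16, 17, 19), (15, 16, 19)):
            site = _design_site(mature, mm, ())
            hit = _verify_site(mature, site)
            if all(hit.rules[:5]) and not hit.rules[5]:
                return mature, site
    raise RuntimeError("could not design a rule-6-failing target site")


def generate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Build the reference bundle with planted ground truth."""
    config.validate()
    rng = np.random.default_rng([config.seed, 101])

    # --- transcriptome scaffold ------------------------------------------------
    lo, hi = config.transcript_len_range
    transcripts: dict[str, str] = {}
    for i in range(config.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        transcripts[f"Unigene{i + 1:05d}"] = _rand_seq(rng, length)
    tids = list(transcripts)

    # --- conserved miRNA reference --------------------------------------------
    n_sites_fam = 7  # families 0-6 carry the designed target-site matures
    matures: list[FastaRecord] = []
    family_of: dict[str, str] = {}
    fail6_mature, fail6_site = _design_fail6_mature(np.random.default_rng([config.seed, 103]))
    for i in range(config.n_conserved_families):
        fam_num = 9001 + i
        if i == 1:
            # rule-1 site needs >= 8 wobble-capable (G/U) bases at positions 13+
            seq = _rand_seq(rng, 12, "ACGU") + _rand_seq(rng, 9, "GU")
        elif i == 5:
            # rule-5 site wobbles miRNA positions 6 and 8
            s = list(_rand_seq(rng, 21, "ACGU"))
            s[5] = "GU"[int(rng.integers(0, 2))]
            s[7] = "GU"[int(rng.integers(0, 2))]
            seq = "".join(s)
        elif i == 6:
            seq = fail6_mature
        else:
            seq = _rand_seq(rng, int(rng.choice([20, 21, 21, 21, 22])), "ACGU")
        rid = f"xsy-miR{fam_num}a"
        matures.append(FastaRecord(id=rid, seq=seq))
        family_of[rid] = f"miR{fam_num}"
    planted_matures = list(matures)
    for i in range(config.n_decoy_families):
        matures.append(FastaRecord(id=f"xsy-miR{9501 + i}a", seq=_rand_seq(rng, 21, "ACGU")))

    # reference precursors for a few families (exercises precursor-based assignment)
    precursors: list[FastaRecord] = []
    prec_rng = np.random.default_rng([config.seed, 104])
    for rec in planted_matures[:8]:
        pre, _ = _build_precursor(prec_rng, normalize_rna(rec.seq), "5p")
        precursors.append(FastaRecord(id=rec.id.replace("miR", "MIR") + "-precursor", seq=pre))

    # --- ncRNA references -------------------------------------------------------
    nc_sizes = {"rRNA": (3, 400, 1600), "tRNA": (5, 70, 90), "snRNA": (3, 100, 200), "snoRNA": (3, 70, 150)}
    ncrna: dict[str, list[FastaRecord]] = {}
    for cat, (n, a, b) in nc_sizes.items():
        ncrna[cat] = [
            FastaRecord(id=f"{cat}_{j + 1}", seq=_rand_seq(rng, int(rng.integers(a, b + 1))))
            for j in range(n)
        ]

    # --- novel precursors planted into transcripts ------------------------------
    planted_precursors: list[PlantedPrecursor] = []
    novel_tids = tids[: config.n_novel]
    for i in range(config.n_novel):
        # nucleotide bias of real matures: U at position 1 and A at position 10 (80%)
        length = int(rng.choice([20, 21, 21, 22]))
        m = list(_rand_seq(rng, length, "ACGU"))
        if rng.random() < 0.8:
            m[0] = "U"
        if rng.random() < 0.8:
            m[9] = "A"
        mature = "".join(m)
        if any(align_ungapped(mature, normalize_rna(r.seq), 2) is not None for r in matures):
            mature = _rand_seq(rng, length, "ACGU")  # defensive; essentially unreachable
        arm = "5p" if i % 2 == 0 else "3p"
        precursor, energy = _build_precursor(rng, mature, arm)
        tid = novel_tids[i]
        t = transcripts[tid]
        pos = int(rng.integers(50, len(t) - len(precursor) - 50))
        pre_dna = precursor.replace("U", "T")
        transcripts[tid] = t[:pos] + pre_dna + t[pos + len(pre_dna):]
        planted_precursors.append(
            PlantedPrecursor(
                precursor_id=f"novel-pre-{i + 1}",
                transcript_id=tid,
                start=pos,
                end=pos + len(pre_dna),
                arm=arm,
                mature=mature,
                precursor_seq=precursor,
                energy=energy,
            )
        )

    # --- planted target sites ----------------------------------------------------
    planted_sites: list[PlantedSite] = []
    site_tids = tids[config.n_novel : config.n_novel + 10]
    de_up = [planted_matures[n_sites_fam + j] for j in range(2)]  # DE families with pass sites

    def site_for(idx: int) -> str:
        return normalize_rna(planted_matures[idx].seq)

    designs: list[tuple[str, str, str]] = [("pass", planted_matures[0].id, _design_site(site_for(0), (), ()))]
    m1 = site_for(1)
    gu_slots = tuple(p for p in range(13, len(m1) + 1) if m1[p - 1] in "GU")[:8]
    designs.append(("fail-rule-1", planted_matures[1].id, _design_site(m1, (), gu_slots)))
    designs.append(("fail-rule-2", planted_matures[2].id, _design_site(site_for(2), (15, 16, 17), ())))
    designs.append(("fail-rule-3", planted_matures[3].id, _design_site(site_for(3), (5, 6), ())))
    designs.append(("fail-rule-4", planted_matures[4].id, _design_site(site_for(4), (10,), ())))
    designs.append(("fail-rule-5", planted_matures[5].id, _design_site(site_for(5), (2, 4), (6, 8))))
    designs.append(("fail-rule-6", planted_matures[6].id, fail6_site))
    for j, rec in enumerate(de_up):
        designs.append(("pass", rec.id, _design_site(normalize_rna(rec.seq), (), ())))

    mature_by_id = {r.id: normalize_rna(r.seq) for r in matures}
    for j, (outcome, mid, site_rna) in enumerate(designs):
        hit = _verify_site(mature_by_id[mid], site_rna)
        if outcome == "pass":
            assert hit.accepted, f"designed pass site rejected: {hit.rules}"
            fail_rule = None
        else:
            fail_rule = int(outcome.split("-")[-1])
            assert not hit.rules[fail_rule - 1], f"designed {outcome} site passes rule {fail_rule}"
            assert not hit.accepted
        tid = site_tids[j]
        t = transcripts[tid]
        site_dna = site_rna.replace("U", "T")
        pos = int(rng.integers(50, len(t) - len(site_dna) - 50))
        transcripts[tid] = t[:pos] + site_dna + t[pos + len(site_dna):]
        planted_sites.append(
            PlantedSite(
                mirna_id=mid,
                mirna=mature_by_id[mid],
                transcript_id=tid,
                start=pos,
                end=pos + len(site_dna),
                outcome=outcome,
                expect_accept=outcome == "pass",
                expect_fail_rule=fail_rule,
            )
        )

    # --- expression truth over tags ----------------------------------------------
    rows: list[dict[str, object]] = []
    de_families: dict[str, float] = {}
    lengths = np.array(sorted(config.insert_length_weights))
    length_p = np.array([config.insert_length_weights[l] for l in lengths], dtype=float)
    length_p /= length_p.sum()

    non_artifact = 1.0 - sum(config.artifact_fractions().values())
    frac_background = non_artifact - (
        config.frac_rrna + config.frac_trna + config.frac_snrna + config.frac_snorna
        + config.frac_conserved + config.frac_novel
    )
    if frac_background <= 0:
        raise ValueError("composition fractions leave no room for background tags")

    def add_tag(tag: str, kind: str, family: str | None, w_leaves: float, w_tri: float) -> None:
        rows.append(
            {"tag": tag, "kind": kind, "family": family,
             "weight_leaves": w_leaves, "weight_trichomes": w_tri}
        )

    # conserved families: log-normal base abundance, 8-fold DE for a designated
    # block.  Up- and down-regulated families are paired on a shared base
    # abundance so the extra multiplied mass balances between the libraries
    # and non-DE families keep comparable within-pool shares.
    de_start = n_sites_fam + 2  # keep site families and pass-site DE families separate
    de_ids = list(range(n_sites_fam, n_sites_fam + 2)) + list(
        range(de_start, de_start + config.n_de_families - 2)
    )
    de_pair_base = {}
    for j in range(0, len(de_ids), 2):
        base = float(max(rng.lognormal(np.log(80.0), 0.5), 60.0))
        for idx in de_ids[j : j + 2]:
            de_pair_base[idx] = base
    n_specific = 6  # families expressed in a single tissue (Venn exclusivity)
    specific_ids = list(range(config.n_conserved_families - n_specific, config.n_conserved_families))
    for i, rec in enumerate(planted_matures):
        family = family_of[rec.id]
        base = float(rng.lognormal(np.log(60.0), 1.0))
        mult_leaves = mult_tri = 1.0
        if i in de_ids:
            base = de_pair_base[i]
            if (de_ids.index(i) % 2) == 0:
                mult_tri = 2.0 ** config.de_log2fc
                de_families[family] = config.de_log2fc
            else:
                mult_leaves = 2.0 ** config.de_log2fc
                de_families[family] = -config.de_log2fc
        elif i in specific_ids:
            if (i - specific_ids[0]) % 2 == 0:
                mult_tri = 0.0
            else:
                mult_leaves = 0.0
        w_l, w_t = base * mult_leaves, base * mult_tri
        mature_rna = normalize_rna(rec.seq)
        if i >= n_sites_fam + 2 + config.n_de_families and i < n_sites_fam + 2 + config.n_de_families + config.n_variant_families:
            # family with an extra 1-mismatch member tag (20% of its reads)
            variant = list(mature_rna)
            p = int(rng.integers(2, len(variant) - 2))
            variant[p] = "ACGU"[("ACGU".index(variant[p]) + int(rng.integers(1, 4))) % 4]
            add_tag(mature_rna, "conserved", family, 0.8 * w_l, 0.8 * w_t)
            add_tag("".join(variant), "conserved_variant", family, 0.2 * w_l, 0.2 * w_t)
        else:
            add_tag(mature_rna, "conserved", family, w_l, w_t)

    # novel matures
    for p in planted_precursors:
        base = float(max(rng.lognormal(np.log(40.0), 0.5), 30.0))
        skew = float(rng.uniform(0.7, 1.4))
        add_tag(p.mature, "novel", None, base, base * skew)

    # ncRNA fragments
    nc_fracs = {"rRNA": config.frac_rrna, "tRNA": config.frac_trna,
                "snRNA": config.frac_snrna, "snoRNA": config.frac_snorna}
    for cat, frac in nc_fracs.items():
        refs = ncrna[cat]
        n_frag = {"rRNA": 25, "tRNA": 15, "snRNA": 6, "snoRNA": 5}[cat]
        for _ in range(n_frag):
            ref = refs[int(rng.integers(0, len(refs)))]
            flen = int(rng.integers(18, 29))
            start = int(rng.integers(0, len(ref.seq) - flen + 1))
            frag = normalize_rna(ref.seq[start : start + flen])
            w = float(rng.lognormal(np.log(8.0), 1.0))
            add_tag(frag, f"ncrna:{cat}", None, w, w * float(rng.uniform(0.6, 1.6)))

    # background tags: mostly transcript substrings, some unmappable
    plain_tids = tids[config.n_novel + 10 :]
    seen_tags = {r["tag"] for r in rows}
    mature_rnas = [normalize_rna(r.seq) for r in matures]
    n_bg = 0
    while n_bg < config.n_background_mapped and plain_tids:
        tid = plain_tids[int(rng.integers(0, len(plain_tids)))]
        t = transcripts[tid]
        flen = int(lengths[int(rng.choice(len(lengths), p=length_p))])
        start = int(rng.integers(0, len(t) - flen + 1))
        tag = normalize_rna(t[start : start + flen])
        if tag in seen_tags or tag.count("A") / len(tag) >= 0.85:
            continue
        if any(align_ungapped(tag, m, 2) is not None for m in mature_rnas):
            continue
        r = float(rng.random())
        w_l = float(rng.lognormal(np.log(4.0), 1.3))
        w_t = float(rng.lognormal(np.log(4.0), 1.3))
        if r < 0.12:
            w_t = 0.0  # leaves-specific
        elif r < 0.24:
            w_l = 0.0
        add_tag(tag, "background", None, w_l, w_t)
        seen_tags.add(tag)
        n_bg += 1
    for _ in range(config.n_background_random):
        flen = int(lengths[int(rng.choice(len(lengths), p=length_p))])
        tag = _rand_seq(rng, flen, "ACGU")
        if tag in seen_tags or tag.count("A") / len(tag) >= 0.85:
            continue
        add_tag(tag, "background_unmapped", None,
                float(rng.lognormal(np.log(3.0), 1.2)), float(rng.lognormal(np.log(3.0), 1.2)))
        seen_tags.add(tag)

    tags_df = pd.DataFrame(rows)
    # scale pool weights to the configured composition fractions per library
    kind_pool = {
        "conserved": config.frac_conserved, "conserved_variant": config.frac_conserved,
        "novel": config.frac_novel,
        "ncrna:rRNA": config.frac_rrna, "ncrna:tRNA": config.frac_trna,
        "ncrna:snRNA": config.frac_snrna, "ncrna:snoRNA": config.frac_snorna,
        "background": frac_background, "background_unmapped": frac_background,
    }
    pool_of = tags_df["kind"].map(
        lambda k: {"conserved_variant": "conserved", "background_unmapped": "background"}.get(k, k)
    )
    for lib in LIBRARIES:
        col = f"weight_{lib}"
        scaled = np.zeros(len(tags_df))
        for pool in pool_of.unique():
            mask = (pool_of == pool).to_numpy()
            total = tags_df.loc[mask, col].sum()
            pool_frac = kind_pool[pool if pool in kind_pool else f"ncrna:{pool}"]
            if total > 0:
                scaled[mask] = tags_df.loc[mask, col] / total * pool_frac
        tags_df[col] = scaled / non_artifact  # weights renormalized over the tag mass

    # --- flat-term annotation ------------------------------------------------------
    annotation: dict[str, set[str]] = {}
    terms = [f"term{j:03d}" for j in range(25)]
    for tid in tids:
        k = int(rng.integers(2, 6))
        annotation[tid] = {terms[int(j)] for j in rng.choice(len(terms), size=k, replace=False)}
    for s in planted_sites:
        annotation[s.transcript_id].add("term_target_site")

    truth = Truth(
        tags=tags_df,
        planted_precursors=planted_precursors,
        planted_sites=planted_sites,
        de_families=de_families,
    )
    bundle = ReferenceBundle(
        transcriptome=transcripts,
        mirna_mature=matures,
        mirna_precursor=precursors,
        ncrna=ncrna,
        truth=truth,
        annotation_map=annotation,
    )
    truth.check(transcripts)
    for p in planted_precursors:
        if p.energy > -18.0:
            raise AssertionError("planted precursor above the energy threshold")
    return bundle


@dataclass
class SimulationResult:
    fastq: dict[str, Path]  # library -> FASTQ path
    truth_counts: pd.DataFrame  # tag, kind, family, count_<library>...
    artifact_counts: pd.DataFrame  # class x library


_A2I = np.full(128, -1, dtype=np.int8)
for _j, _b in enumerate(_DNA):
    _A2I[ord(_b)] = _j
_I2A = np.frombuffer(_DNA.encode(), dtype=np.uint8)


def _read_template(insert_dna: str, config: SimulationConfig) -> str:
    pad = (config.adapter3 + "CGTATGCCGTCTTCTGCTTGAAAAAAAAAA") * 3
    return (insert_dna + pad)[: config.read_length]


class _FastqWriter:
    def __init__(self, path: Path, library: str, config: SimulationConfig, rng: np.random.Generator):
        self.fh = open(path, "w")
        self.library = library
        self.config = config
        self.rng = rng
        self.i = 0

    def emit(self, template: str, count: int, force_low_quality: bool = False) -> None:
        if count <= 0:
            return
        cfg = self.config
        L = cfg.read_length
        codes = np.tile(np.frombuffer(template.encode(), dtype=np.uint8), (count, 1))
        quals = np.rint(self.rng.normal(cfg.qual_mean, cfg.qual_sd, (count, L))).astype(np.int16)
        quals = np.clip(quals, 2, 40)
        err = self.rng.random((count, L)) < 10.0 ** (-quals / 10.0)
        if err.any():
            r, c = np.nonzero(err)
            old = _A2I[codes[r, c]].astype(np.int64)
            codes[r, c] = _I2A[(old + self.rng.integers(1, 4, r.size)) % 4]
        if force_low_quality:
            # >4 bases below Q10 triggers the low-quality filter
            for row in range(count):
                pos = self.rng.choice(L, size=6, replace=False)
                quals[row, pos] = self.rng.integers(2, 10, 6)
        qcodes = (quals + cfg.phred_offset).astype(np.uint8)
        parts = []
        for row in range(count):
            parts.append(
                f"@{self.library}_{self.i + row}\n{codes[row].tobytes().decode()}\n+\n{qcodes[row].tobytes().decode()}\n"
            )
        self.fh.write("".join(parts))
        self.i += count

    def close(self) -> None:
        self.fh.close()


def _artifact_template(cls: str, config: SimulationConfig, rng: np.random.Generator,
                       insert_pool: list[str], clean_cfg: CleanConfig) -> tuple[str, bool]:
    """Template read for one artifact class; returns (template, force_low_quality)."""
    insert = insert_pool[int(rng.integers(0, len(insert_pool)))]
    if cls == "low_quality":
        return _read_template(insert, config), True
    if cls == "adapter5":
        return (config.adapter5 + insert + config.adapter3 * 3)[: config.read_length], False
    if cls == "no_adapter3":
        for _ in range(50):
            tail = _rand_seq(rng, config.read_length)
            read = (insert + tail)[: config.read_length]
            if find_adapter3(read, clean_cfg) is None:
                return read, False
        raise RuntimeError("could not build an adapter-free read")
    if cls == "adapter_dimer":
        return _read_template("", config), False
    if cls == "polya":
        return _read_template("A" * int(rng.integers(18, 26)), config), False
    if cls == "short":
        while True:
            ins = _rand_seq(rng, int(rng.integers(10, 18)))
            if ins.count("A") / len(ins) < 0.9:
                return _read_template(ins, config), False
    raise ValueError(f"unknown artifact class {cls!r}")


def simulate_libraries(
    bundle: ReferenceBundle, config: SimulationConfig, out_dir: str | os.PathLike
) -> SimulationResult:
    """Sample and write the two FASTQ libraries plus the truth count table."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clean_cfg = CleanConfig(adapter3=config.adapter3, adapter5=config.adapter5)
    tags = bundle.truth.tags.copy()
    insert_pool = [t.replace("U", "T") for t in tags["tag"].head(80)] or ["ACGTACGTACGTACGTACGTACGT"]
    art_fracs = config.artifact_fractions()
    art_names = list(art_fracs)
    fastq: dict[str, Path] = {}
    art_rows = []
    for lib_index, lib in enumerate(LIBRARIES):
        rng = np.random.default_rng([config.seed, 211 + lib_index])
        weights = tags[f"weight_{lib}"].to_numpy(dtype=float)
        tag_mass = 1.0 - sum(art_fracs.values())
        if weights.sum() <= 0:
            raise ValueError(f"no positive tag weights for library {lib}")
        probs = np.concatenate([weights / weights.sum() * tag_mass, [art_fracs[a] for a in art_names]])
        counts = rng.multinomial(config.n_reads, probs / probs.sum())
        tag_counts, art_counts = counts[: len(tags)], counts[len(tags):]
        tags[f"count_{lib}"] = tag_counts
        art_rows.append(dict(zip(art_names, (int(x) for x in art_counts)), library=lib))

        path = out / f"{lib}.fastq"
        writer = _FastqWriter(path, lib, config, rng)
        for tag, n in zip(tags["tag"], tag_counts):
            if n:
                writer.emit(_read_template(tag.replace("U", "T"), config), int(n))
        for cls, n in zip(art_names, art_counts):
            for _ in range(int(n)):
                template, force_lq = _artifact_template(cls, config, rng, insert_pool, clean_cfg)
                writer.emit(template, 1, force_low_quality=force_lq)
        writer.close()
        fastq[lib] = path
        assert int(tag_counts.sum() + art_counts.sum()) == config.n_reads

    truth_counts = tags[["tag", "kind", "family"] + [f"count_{lib}" for lib in LIBRARIES]]
    truth_counts.to_csv(out / "truth_counts.tsv", sep="\t", index=False)
    artifact_counts = pd.DataFrame(art_rows)
    artifact_counts.to_csv(out / "artifact_counts.tsv", sep="\t", index=False)
    return SimulationResult(fastq=fastq, truth_counts=truth_counts, artifact_counts=artifact_counts)
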