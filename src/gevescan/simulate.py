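"""Synthetic two-strain genome generator with planted ground truth.

Strain B derives from strain A's backbone by i.i.d. per-site substitution
(uniform replacement) at a configured rate; each strain additionally carries
strain-specific multi-gene "viral" insertions biased toward chromosome ends,
optional partial duplicate copies of those insertions, non-viral divergent
segments, mobile elements, telomeric unit arrays, hypermethylated insertion
bodies and transcriptionally suppressed insertion genes.

The inter-strain alignment (blocks + diff records) is derived analytically
from the simulation history, so the planted truth is exact: no aligner runs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as gio
from .io import GeneModel

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
STOP_CODONS = ("TAA", "TAG", "TGA")

SELF_GENUS = "Amoebozoon"
VIRAL_GENERA = ("Alphagigavirus", "Betagigavirus", "Gammagigavirus")
CELLULAR_GENERA = ("Bacillus", "Dictyostelium", "Saccharomyces", "Arabidopsis")
MOBILE_CLASSES = ("LTR", "LINE", "DNA_transposon")


class ConfigurationError(ValueError):
    pass


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an insertion."""


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chromosome_lengths: tuple[int, ...] = (1_500_000, 1_200_000, 1_000_000, 800_000)
    background_divergence: float = 0.15
    gene_density: float = 0.25          # host genes per kbp of backbone
    n_viral_insertions_per_strain: int = 8
    insertion_length: tuple[int, int] = (20_000, 80_000)
    subtelomeric_bias: float = 0.8      # probability mass in the terminal fraction
    terminal_fraction: float = 0.1
    duplication_fraction: float = 0.25  # insertions with a partial second copy
    mobile_element_rate: float = 2.0    # mobile elements per viral insertion
    background_mobile_per_mbp: float = 5.0
    n_nonviral_insertions_per_strain: int = 3
    telomere_units: int = 20            # TTAGGG copies at each chromosome end
    methylation_background_mean: float = 0.02
    methylation_viral_mean: float = 0.8
    expression_background: float = 50.0  # TPM-scale lognormal location
    expression_viral: float = 0.5
    hit_noise: float = 0.0              # probability a gene's hit profile is mislabeled
    coverage_mean: float = 20.0         # mean per-CpG nanopore coverage
    host_gc: float = 0.55
    viral_gc: float = 0.35
    hic_bin_size: int = 10_000
    hic_compaction: float = 2.0
    max_placement_retries: int = 500

    def validate(self) -> None:
        probs = {
            "background_divergence": self.background_divergence,
            "subtelomeric_bias": self.subtelomeric_bias,
            "terminal_fraction": self.terminal_fraction,
            "duplication_fraction": self.duplication_fraction,
            "methylation_background_mean": self.methylation_background_mean,
            "methylation_viral_mean": self.methylation_viral_mean,
            "hit_noise": self.hit_noise,
            "host_gc": self.host_gc,
            "viral_gc": self.viral_gc,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ConfigurationError("chromosome_lengths length != n_chromosomes")
        if any(length <= 0 for length in self.chromosome_lengths):
            raise ConfigurationError("chromosome lengths must be positive")
        lo, hi = self.insertion_length
        if not 0 < lo <= hi:
            raise ConfigurationError(f"bad insertion_length range ({lo}, {hi})")
        if self.n_viral_insertions_per_strain > 0 and hi >= min(self.chromosome_lengths):
            raise ConfigurationError("insertion longer than the shortest chromosome")
        if self.methylation_viral_mean <= self.methylation_background_mean:
            raise ConfigurationError("viral methylation mean must exceed background mean")


@dataclass
class StrainPairTruth:
    """Planted ground truth for one simulated strain pair."""

    insertions: pd.DataFrame       # strain chromosome start end donor kind id source_id
    genes: pd.DataFrame            # strain gene_id chromosome start end strand origin
                                   #   conserved methylation_state expression_tier expression_rate
    mobile_elements: pd.DataFrame  # strain chromosome start end class context
    duplication_links: pd.DataFrame  # strain src_id dst_id


@dataclass
class StrainPair:
    config: SimulationConfig
    sequences: dict[str, dict[str, str]]       # strain -> chromosome -> sequence
    genes: dict[str, list[GeneModel]]
    truth: StrainPairTruth
    blocks: pd.DataFrame
    diff: pd.DataFrame


# ---------------------------------------------------------------------------
# sequence helpers

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=length, p=p)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _substitute(rng: np.random.Generator, seq: np.ndarray, rate: float,
                protect: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-replacement substitutions outside the terminal `protect` bp."""
    out = seq.copy()
    if rate <= 0:
        return out, np.empty(0, dtype=np.int64)
    mask = rng.random(len(seq)) < rate
    if protect > 0:
        mask[:protect] = False
        mask[len(seq) - protect:] = False
    pos = np.flatnonzero(mask)
    # replace with one of the three other bases, uniformly
    idx = np.searchsorted(BASES, out[pos])
    shift = rng.integers(1, 4, size=len(pos))
    out[pos] = BASES[(idx + shift) % 4]
    return out, pos


# ---------------------------------------------------------------------------
# insertion content

def _tile_genes(rng: np.random.Generator, length: int, orphan_fraction: float
                ) -> list[tuple[int, int, str, str]]:
    """Tile (start, end, strand, origin) gene intervals across an insertion."""
    out = []
    pos = int(rng.integers(150, 400))
    while True:
        glen = int(rng.integers(200, 500)) * 3
        gap = int(rng.integers(150, 400))
        if pos + glen + 150 > length:
            break
        origin = "orphan" if rng.random() < orphan_fraction else "viral"
        strand = "+" if rng.random() < 0.5 else "-"
        out.append((pos, pos + glen, strand, origin))
        pos += glen + gap
    return out


def _build_insertion(rng: np.random.Generator, length: int, donor: str,
                     cfg: SimulationConfig) -> dict:
    seq = _random_seq(rng, length, cfg.viral_gc)
    genes = _tile_genes(rng, length, orphan_fraction=0.3)
    n_me = rng.poisson(cfg.mobile_element_rate)
    mes = []
    for _ in range(n_me):
        mlen = int(rng.integers(300, 1500))
        if mlen >= length:
            continue
        ms = int(rng.integers(0, length - mlen))
        mes.append((ms, ms + mlen, MOBILE_CLASSES[rng.integers(0, len(MOBILE_CLASSES))]))
    return {"seq": seq, "genes": genes, "mobile": mes, "donor": donor, "kind": "viral"}


# ---------------------------------------------------------------------------
# placement

def _sample_point(rng: np.random.Generator, length: int, cfg: SimulationConfig,
                  margin: int) -> int:
    lo, hi = margin, length - margin
    if hi <= lo:
        raise ConfigurationError("chromosome too short for telomere margins")
    if rng.random() < cfg.subtelomeric_bias:
        tlen = max(1, int(cfg.terminal_fraction * length))
        left = (lo, min(hi, lo + tlen))
        right = (max(lo, hi - tlen), hi)
        a, b = left if rng.random() < 0.5 else right
        return int(rng.integers(a, max(a + 1, b)))
    return int(rng.integers(lo, hi))


def _place_insertions(rng: np.random.Generator, cfg: SimulationConfig,
                      host_genes: dict[str, list[tuple[int, int]]],
                      requests: list[dict], margin: int,
                      occupied: dict[str, list[int]]) -> list[dict]:
    """Assign (chromosome, backbone point) to each insertion request."""
    lengths = np.asarray(cfg.chromosome_lengths, dtype=float)
    chrom_names = [f"chr{i + 1:02d}" for i in range(cfg.n_chromosomes)]
    p_chrom = lengths / lengths.sum()
    placed = []
    for req in requests:
        for attempt in range(cfg.max_placement_retries):
            ci = int(rng.choice(cfg.n_chromosomes, p=p_chrom))
            chrom = chrom_names[ci]
            point = _sample_point(rng, cfg.chromosome_lengths[ci], cfg, margin)
            # reject inside host genes
            if any(s < point < e for s, e in host_genes[chrom]):
                continue
            # reject too close to other insertion points (either strain)
            if any(abs(point - q) < 1000 for q in occupied[chrom]):
                continue
            occupied[chrom].append(point)
            placed.append({**req, "chromosome": chrom, "point": point})
            break
        else:
            raise PlacementError(
                f"could not place insertion after {cfg.max_placement_retries} retries")
    return placed


# ---------------------------------------------------------------------------
# main simulation

def simulate_strain_pair(config: SimulationConfig) -> StrainPair:
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    rng_seq, rng_place, rng_content, rng_extra = rngs

    chrom_names = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    tel = "TTAGGG" * config.telomere_units
    tel_len = len(tel)
    tel_left = np.frombuffer(("CCCTAA" * config.telomere_units).encode(), dtype=np.uint8)
    tel_right = np.frombuffer(tel.encode(), dtype=np.uint8)

    # backbone (strain A) and substituted backbone (strain B)
    backbone: dict[str, np.ndarray] = {}
    backbone_b: dict[str, np.ndarray] = {}
    sub_positions: dict[str, np.ndarray] = {}
    for name, L in zip(chrom_names, config.chromosome_lengths):
        if L <= 2 * tel_len + 2000:
            raise ConfigurationError(f"chromosome {name} too short ({L} bp)")
        core = _random_seq(rng_seq, L - 2 * tel_len, config.host_gc)
        arr = np.concatenate([tel_left, core, tel_right])
        backbone[name] = arr
        mutated, pos = _substitute(rng_seq, arr, config.background_divergence, tel_len)
        backbone_b[name] = mutated
        sub_positions[name] = pos

    # host genes along the backbone (shared between strains)
    host_genes: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chrom_names}
    mean_gap = max(200.0, 1000.0 / max(config.gene_density, 1e-9) - 1300.0)
    for name, L in zip(chrom_names, config.chromosome_lengths):
        pos = tel_len + 500
        while True:
            pos += int(rng_place.exponential(mean_gap)) + 50
            glen = int(rng_place.integers(300, 600)) * 3
            if pos + glen > L - tel_len - 500:
                break
            strand = "+" if rng_place.random() < 0.5 else "-"
            host_genes[name].append((pos, pos + glen, strand))
            pos += glen

    host_spans = {c: [(s, e) for s, e, _ in host_genes[c]] for c in chrom_names}

    # insertion requests per strain: viral, duplicate copies, non-viral
    occupied: dict[str, list[int]] = {c: [] for c in chrom_names}
    strain_insertions: dict[str, list[dict]] = {}
    dup_links: list[dict] = []
    ins_counter = 0
    for strain in ("A", "B"):
        requests = []
        for _ in range(config.n_viral_insertions_per_strain):
            ilen = int(rng_content.integers(config.insertion_length[0],
                                            config.insertion_length[1] + 1))
            donor = VIRAL_GENERA[rng_content.integers(0, len(VIRAL_GENERA))]
            ins = _build_insertion(rng_content, ilen, donor, config)
            ins["id"] = f"{strain}_ins{ins_counter:03d}"
            ins["source_id"] = ""
            ins_counter += 1
            requests.append(ins)
        # partial duplicate copies of some viral insertions
        for ins in list(requests):
            if rng_content.random() < config.duplication_fraction:
                ilen = len(ins["seq"])
                span = int(ilen * rng_content.uniform(0.3, 0.6))
                off = int(rng_content.integers(0, ilen - span))
                sub = ins["seq"][off:off + span].copy()
                genes = [(s - off, e - off, st, orig) for s, e, st, orig in ins["genes"]
                         if s >= off and e <= off + span]
                mes = [(s - off, e - off, cls) for s, e, cls in ins["mobile"]
                       if s >= off and e <= off + span]
                dup = {"seq": sub, "genes": genes, "mobile": mes,
                       "donor": ins["donor"], "kind": "dup_copy",
                       "id": f"{strain}_ins{ins_counter:03d}", "source_id": ins["id"]}
                ins_counter += 1
                requests.append(dup)
                dup_links.append({"strain": strain, "src_id": ins["id"], "dst_id": dup["id"]})
        for _ in range(config.n_nonviral_insertions_per_strain):
            nlen = int(rng_content.integers(2_000, 10_000))
            seq = _random_seq(rng_content, nlen, config.host_gc)
            mes = []
            if rng_content.random() < 0.5 and nlen > 1500:
                mlen = int(rng_content.integers(300, 1200))
                ms = int(rng_content.integers(0, nlen - mlen))
                mes.append((ms, ms + mlen,
                            MOBILE_CLASSES[rng_content.integers(0, len(MOBILE_CLASSES))]))
            requests.append({"seq": seq, "genes": [], "mobile": mes, "donor": "",
                             "kind": "nonviral", "id": f"{strain}_ins{ins_counter:03d}",
                             "source_id": ""})
            ins_counter += 1
        strain_insertions[strain] = _place_insertions(
            rng_place, config, host_spans, requests, tel_len + 1000, occupied)

    # assemble final sequences and coordinate maps
    sequences: dict[str, dict[str, str]] = {"A": {}, "B": {}}
    gene_models: dict[str, list[GeneModel]] = {"A": [], "B": []}
    truth_ins_rows, truth_gene_rows, truth_me_rows = [], [], []
    diff_rows, block_rows = [], []
    offsets: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    counters = {"A": {"host": 0, "viral": 0, "orphan": 0},
                "B": {"host": 0, "viral": 0, "orphan": 0}}

    for strain in ("A", "B"):
        base = backbone if strain == "A" else backbone_b
        for chrom in chrom_names:
            ins_here = sorted((i for i in strain_insertions[strain]
                               if i["chromosome"] == chrom), key=lambda d: d["point"])
            points = np.array([i["point"] for i in ins_here], dtype=np.int64)
            lens = np.array([len(i["seq"]) for i in ins_here], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(lens)])
            offsets[(strain, chrom)] = (points, cum)

            parts, prev = [], 0
            for ins, p in zip(ins_here, points):
                parts.append(base[chrom][prev:p])
                parts.append(ins["seq"])
                prev = p
            parts.append(base[chrom][prev:])
            final = np.concatenate(parts) if parts else base[chrom]
            sequences[strain][chrom] = _to_str(final)

            # insertion coordinates in final frame, plus their genes/MEs
            for k, ins in enumerate(ins_here):
                fstart = int(points[k] + cum[k])
                fend = fstart + int(lens[k])
                truth_ins_rows.append({
                    "strain": strain, "chromosome": chrom, "start": fstart,
                    "end": fend, "donor": ins["donor"], "kind": ins["kind"],
                    "id": ins["id"], "source_id": ins["source_id"]})
                gene_ends = []
                for s, e, st, orig in ins["genes"]:
                    counters[strain][orig] += 1
                    gid = f"{strain}_{orig[0]}{counters[strain][orig]:05d}"
                    gene_models[strain].append(GeneModel(
                        id=gid, chromosome=chrom, start=fstart + s, end=fstart + e,
                        strand=st, kind="annotated_gene",
                        intron_count=int(rng_extra.poisson(0.3))))
                    rate = float(rng_extra.lognormal(np.log(config.expression_viral), 0.6))
                    truth_gene_rows.append({
                        "strain": strain, "gene_id": gid, "chromosome": chrom,
                        "start": fstart + s, "end": fstart + e, "strand": st,
                        "origin": orig, "conserved": False,
                        "methylation_state": config.methylation_viral_mean,
                        "expression_tier": "suppressed", "expression_rate": rate})
                    gene_ends.append((s, e))
                for s, e, cls in ins["mobile"]:
                    truth_me_rows.append({
                        "strain": strain, "chromosome": chrom, "start": fstart + s,
                        "end": fstart + e, "class": cls,
                        "context": "viral_region" if ins["kind"] in ("viral", "dup_copy")
                        else "other_divergent"})

                # diff records for this strain-specific insertion
                if ins["kind"] == "dup_copy":
                    diff_rows.append({"strain": strain, "chromosome": chrom,
                                      "category": "DUP", "start": fstart, "end": fend})
                elif ins["kind"] == "nonviral":
                    diff_rows.append({"strain": strain, "chromosome": chrom,
                                      "category": "GAP", "start": fstart, "end": fend})
                else:
                    diff_rows.extend(_split_viral_diff(
                        rng_extra, strain, chrom, fstart, fend, gene_ends))

            # host genes mapped into this strain's final frame
            for s, e, st in host_genes[chrom]:
                off = int(cum[np.searchsorted(points, s, side="right")])
                counters[strain]["host"] += 1
                gid = f"{strain}_h{counters[strain]['host']:05d}"
                gene_models[strain].append(GeneModel(
                    id=gid, chromosome=chrom, start=s + off, end=e + off, strand=st,
                    kind="annotated_gene", intron_count=int(rng_extra.poisson(3.0))))
                rate = float(rng_extra.lognormal(np.log(config.expression_background), 0.8))
                truth_gene_rows.append({
                    "strain": strain, "gene_id": gid, "chromosome": chrom,
                    "start": s + off, "end": e + off, "strand": st, "origin": "host",
                    "conserved": True,
                    "methylation_state": config.methylation_background_mean,
                    "expression_tier": "background", "expression_rate": rate})

    # background mobile elements in aligned backbone
    for strain in ("A", "B"):
        for chrom, L in zip(chrom_names, config.chromosome_lengths):
            points, cum = offsets[(strain, chrom)]
            n_bg = rng_extra.poisson(config.background_mobile_per_mbp * L / 1e6)
            for _ in range(n_bg):
                mlen = int(rng_extra.integers(300, 1500))
                s = int(rng_extra.integers(tel_len, L - tel_len - mlen))
                k = np.searchsorted(points, s, side="right")
                if k > 0 and s < points[k - 1] + 1 and s > points[k - 1] - mlen:
                    continue  # touching an insertion point; skip for clean context
                off = int(cum[k])
                truth_me_rows.append({
                    "strain": strain, "chromosome": chrom, "start": s + off,
                    "end": s + mlen + off, "class":
                        MOBILE_CLASSES[rng_extra.integers(0, len(MOBILE_CLASSES))],
                    "context": "conserved_background"})

    # alignment blocks: backbone cut at every insertion point of either strain
    for chrom, L in zip(chrom_names, config.chromosome_lengths):
        pa, ca = offsets[("A", chrom)]
        pb, cb = offsets[("B", chrom)]
        cuts = np.unique(np.concatenate([[0], pa, pb, [L]]))
        subs = sub_positions[chrom]
        for u, v in zip(cuts[:-1], cuts[1:]):
            if v <= u:
                continue
            off_a = int(ca[np.searchsorted(pa, u, side="right")])
            off_b = int(cb[np.searchsorted(pb, u, side="right")])
            n_sub = int(np.searchsorted(subs, v) - np.searchsorted(subs, u))
            pid = 100.0 * (1.0 - n_sub / (v - u))
            block_rows.append({
                "ref_chromosome": chrom, "ref_start": int(u + off_a),
                "ref_end": int(v + off_a), "query_chromosome": chrom,
                "query_start": int(u + off_b), "query_end": int(v + off_b),
                "pident": round(pid, 4)})

    # a few INV records far from insertions, to exercise concatenation breakers
    for strain in ("A", "B"):
        for _ in range(2):
            ci = int(rng_extra.integers(0, config.n_chromosomes))
            chrom, L = chrom_names[ci], config.chromosome_lengths[ci]
            points, cum = offsets[(strain, chrom)]
            s = int(rng_extra.integers(tel_len, L - tel_len - 1000))
            if len(points) and np.min(np.abs(points - s)) < 5000:
                continue
            off = int(cum[np.searchsorted(points, s, side="right")])
            diff_rows.append({"strain": strain, "chromosome": chrom,
                              "category": "INV", "start": s + off, "end": s + off + 1000})

    ins_cols = ["strain", "chromosome", "start", "end", "donor", "kind", "id", "source_id"]
    gene_cols = ["strain", "gene_id", "chromosome", "start", "end", "strand", "origin",
                 "conserved", "methylation_state", "expression_tier", "expression_rate"]
    me_cols = ["strain", "chromosome", "start", "end", "class", "context"]
    truth = StrainPairTruth(
        insertions=pd.DataFrame(truth_ins_rows, columns=ins_cols),
        genes=pd.DataFrame(truth_gene_rows, columns=gene_cols),
        mobile_elements=pd.DataFrame(truth_me_rows, columns=me_cols),
        duplication_links=pd.DataFrame(dup_links, columns=["strain", "src_id", "dst_id"]),
    )
    for strain in ("A", "B"):
        gene_models[strain].sort(key=lambda g: (g.chromosome, g.start))
    blocks = pd.DataFrame(block_rows, columns=gio.BLOCK_COLUMNS)
    diff = pd.DataFrame(diff_rows, columns=gio.DIFF_COLUMNS).sort_values(
        ["strain", "chromosome", "start"]).reset_index(drop=True)
    return StrainPair(config=config, sequences=sequences, genes=gene_models,
                      truth=truth, blocks=blocks, diff=diff)


def _split_viral_diff(rng: np.random.Generator, strain: str, chrom: str,
                      fstart: int, fend: int,
                      gene_ends: list[tuple[int, int]]) -> list[dict]:
    """Diff records covering a viral insertion.

    With probability 1/2 the record is a single GAP; otherwise an intergenic
    chunk inside the insertion is emitted as DUP or JMP flanked by two GAPs
    (contiguous), mimicking gaps interrupted by duplications/translocations.
    The non-GAP chunk is kept within intergenic space so that every planted
    gene still lies entirely within the union of GAP records.
    """
    rows = [{"strain": strain, "chromosome": chrom, "category": "GAP",
             "start": fstart, "end": fend}]
    if rng.random() < 0.5 or len(gene_ends) < 2:
        return rows
    # pick a gap between two consecutive genes
    k = int(rng.integers(0, len(gene_ends) - 1))
    lo = gene_ends[k][1]
    hi = gene_ends[k + 1][0]
    if hi - lo < 60:
        return rows
    a = int(rng.integers(lo, hi - 50))
    b = int(rng.integers(a + 30, hi))
    cat = "DUP" if rng.random() < 0.5 else "JMP"
    return [
        {"strain": strain, "chromosome": chrom, "category": "GAP",
         "start": fstart, "end": fstart + a},
        {"strain": strain, "chromosome": chrom, "category": cat,
         "start": fstart + a, "end": fstart + b},
        {"strain": strain, "chromosome": chrom, "category": "GAP",
         "start": fstart + b, "end": fend},
    ]


# ---------------------------------------------------------------------------
# evidence-file emission

def _subject_pool() -> pd.DataFrame:
    rows = []
    for g in VIRAL_GENERA:
        for i in range(30):
            rows.append((f"{g[:5].upper()}_{i:03d}", "Viruses", g))
    for g in CELLULAR_GENERA:
        for i in range(30):
            sk = "Bacteria" if g == "Bacillus" else "Eukaryota"
            rows.append((f"{g[:5].upper()}_{i:03d}", sk, g))
    for i in range(20):
        rows.append((f"SELF_{i:03d}", "Eukaryota", SELF_GENUS))
    return pd.DataFrame(rows, columns=gio.TAXONOMY_COLUMNS)


def _emit_hits_for_gene(rng: np.random.Generator, gid: str, glen: int,
                        profile: str, donor: str, taxonomy: pd.DataFrame) -> list[tuple]:
    """Emit an outfmt-6 hit list for one gene according to its profile."""
    subjects = taxonomy["sseqid"].to_numpy()
    genus = taxonomy["genus"].to_numpy()
    sk = taxonomy["superkingdom"].to_numpy()
    viral_idx = np.flatnonzero(sk == "Viruses")
    donor_idx = np.flatnonzero(genus == donor) if donor else viral_idx
    cell_idx = np.flatnonzero((sk != "Viruses") & (genus != SELF_GENUS))
    self_idx = np.flatnonzero(genus == SELF_GENUS)

    picks: list[int] = []
    if profile == "viral":
        picks += list(rng.choice(donor_idx, size=4, replace=False))
        picks += list(rng.choice(viral_idx, size=3, replace=False))
        picks += list(rng.choice(cell_idx, size=3, replace=False))
    elif profile == "host":
        picks += list(rng.choice(cell_idx, size=10, replace=False))
        if rng.random() < 0.3:  # an occasional lower-rank viral hit
            k = int(rng.integers(1, 10))
            picks.insert(k, int(rng.choice(viral_idx)))
    else:
        return []
    rows = []
    bitscore = float(rng.uniform(350, 450))
    evalue = 10.0 ** -float(rng.uniform(40, 60))
    for rank, si in enumerate(picks):
        alen = max(30, glen // 3 - int(rng.integers(0, 20)))
        rows.append((gid, subjects[si], round(float(rng.uniform(30, 90)), 1), alen,
                     int(rng.integers(0, alen // 3)), int(rng.integers(0, 3)),
                     1, alen, 1, alen, evalue, round(bitscore, 1)))
        bitscore -= float(rng.uniform(5, 30))
        evalue *= 10.0 ** float(rng.uniform(1, 4))
    # self-genus hits with top bitscore: must be filtered out downstream
    for si in rng.choice(self_idx, size=2, replace=False):
        alen = max(30, glen // 3)
        rows.append((gid, subjects[si], 95.0, alen, 1, 0, 1, alen, 1, alen,
                     1e-80, 900.0))
    return rows


def emit_evidence_files(pair: StrainPair, outdir: str | os.PathLike,
                        methylation_sampling: bool = True) -> dict[str, str]:
    """Write every downstream evidence file for a simulated pair.

    Returns a manifest of logical name -> path.  Deterministic given the
    pair's config seed.
    """
    cfg = pair.config
    os.makedirs(outdir, exist_ok=True)
    out = lambda name: os.path.join(str(outdir), name)
    ss = np.random.SeedSequence([cfg.seed, 7])
    rng_hits, rng_meth, rng_expr, rng_hic = (
        np.random.default_rng(s) for s in ss.spawn(4))
    manifest: dict[str, str] = {}

    taxonomy = _subject_pool()
    gio.write_taxonomy(taxonomy, out("taxonomy.tsv"))
    manifest["taxonomy"] = out("taxonomy.tsv")
    gio.write_blocks(pair.blocks, out("blocks.tsv"))
    gio.write_diff(pair.diff, out("diff.tsv"))
    manifest["blocks"] = out("blocks.tsv")
    manifest["diff"] = out("diff.tsv")

    donor_by_gene: dict[str, str] = {}
    for _, g in pair.truth.genes.iterrows():
        donor_by_gene[g.gene_id] = ""
    for _, ins in pair.truth.insertions.iterrows():
        sel = (pair.truth.genes.strain == ins.strain) & \
              (pair.truth.genes.chromosome == ins.chromosome) & \
              (pair.truth.genes.start >= ins.start) & (pair.truth.genes.end <= ins.end)
        for gid in pair.truth.genes.loc[sel, "gene_id"]:
            donor_by_gene[gid] = ins.donor

    for strain in ("A", "B"):
        seqs = pair.sequences[strain]
        genes = pair.genes[strain]
        gio.write_fasta(seqs, out(f"{strain}.fasta"))
        gio.write_gff3_genes(genes, out(f"{strain}.genes.gff3"))
        manifest[f"{strain}.fasta"] = out(f"{strain}.fasta")
        manifest[f"{strain}.gff"] = out(f"{strain}.genes.gff3")

        tg = pair.truth.genes[pair.truth.genes.strain == strain].set_index("gene_id")

        # homology hits
        hit_rows: list[tuple] = []
        for g in genes:
            origin = tg.loc[g.id, "origin"]
            profile = {"host": "host", "viral": "viral", "orphan": "orphan"}[origin]
            if profile != "orphan" and rng_hits.random() < cfg.hit_noise:
                profile = "viral" if profile == "host" else "host"
            hit_rows.extend(_emit_hits_for_gene(
                rng_hits, g.id, g.length, profile, donor_by_gene.get(g.id, ""), taxonomy))
        hits = pd.DataFrame(hit_rows, columns=gio.HITS_COLUMNS)
        gio.write_hits(hits, out(f"{strain}.hits.tsv"))
        manifest[f"{strain}.hits"] = out(f"{strain}.hits.tsv")

        # hallmark-gene hits: up to two per viral insertion, never the full
        # suite (VLTF3 and SFII are deliberately absent everywhere)
        hm_rows = []
        for _, ins in pair.truth.insertions.iterrows():
            if ins.strain != strain or ins.kind != "viral":
                continue
            vsel = tg[(tg.chromosome == ins.chromosome) & (tg.origin == "viral")
                      & (tg.start >= ins.start) & (tg.end <= ins.end)]
            n_hm = min(len(vsel), int(rng_hits.integers(0, 3)))
            if n_hm == 0:
                continue
            chosen = rng_hits.choice(len(vsel), size=n_hm, replace=False)
            labels = rng_hits.choice(["MCP", "A32_ATPase", "polB"], size=n_hm,
                                     replace=False)
            for ci, lab in zip(chosen, labels):
                row = vsel.iloc[ci]
                hm_rows.append((row.chromosome, int(row.start), int(row.end),
                                lab, 10.0 ** -float(rng_hits.uniform(6, 20))))
        pd.DataFrame(hm_rows, columns=[
            "chromosome", "start", "end", "hallmark", "evalue"]).to_csv(
            out(f"{strain}.hallmarks.tsv"), sep="\t", index=False)
        manifest[f"{strain}.hallmarks"] = out(f"{strain}.hallmarks.tsv")

        # methylation: planted fraction by position (insertion bodies elevated)
        ins_s = pair.truth.insertions[(pair.truth.insertions.strain == strain)
                                      & (pair.truth.insertions.kind != "nonviral")]
        meth_frames = []
        for chrom, seq in seqs.items():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            cg = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
            frac = np.full(len(cg), cfg.methylation_background_mean)
            for _, ins in ins_s[ins_s.chromosome == chrom].iterrows():
                frac[(cg >= ins.start) & (cg < ins.end)] = cfg.methylation_viral_mean
            pos = np.concatenate([cg, cg + 1])
            strand = np.array(["+"] * len(cg) + ["-"] * len(cg))
            fr = np.concatenate([frac, frac])
            if methylation_sampling:
                cov = rng_meth.poisson(cfg.coverage_mean, size=len(pos))
                keep = cov > 0
                pos, strand, fr, cov = pos[keep], strand[keep], fr[keep], cov[keep]
                met = rng_meth.binomial(cov, fr)
            else:
                cov = np.full(len(pos), int(round(cfg.coverage_mean)))
                met = np.rint(fr * cov).astype(int)
            order = np.argsort(pos, kind="stable")
            meth_frames.append(pd.DataFrame({
                "chromosome": chrom, "position": pos[order], "strand": strand[order],
                "coverage": cov[order], "methylated_count": met[order]}))
        meth = pd.concat(meth_frames, ignore_index=True)
        gio.write_bedmethyl(meth, out(f"{strain}.methylation.tsv"))
        manifest[f"{strain}.methylation"] = out(f"{strain}.methylation.tsv")

        # expression counts (per gene) and coverage bedGraph
        count_rows = []
        for g in genes:
            rate = float(tg.loc[g.id, "expression_rate"])
            lam = rate * (g.length / 1000.0) * 2.0
            count_rows.append((g.id, int(rng_expr.poisson(lam)), g.length))
        counts = pd.DataFrame(count_rows, columns=gio.COUNTS_COLUMNS)
        gio.write_counts(counts, out(f"{strain}.counts.tsv"))
        manifest[f"{strain}.counts"] = out(f"{strain}.counts.tsv")

        cov_frames = []
        binw = 250
        for chrom, seq in seqs.items():
            nb = (len(seq) + binw - 1) // binw
            lam = np.full(nb, 0.3)
            for g in genes:
                if g.chromosome != chrom:
                    continue
                rate = float(tg.loc[g.id, "expression_rate"])
                lam[g.start // binw:(g.end - 1) // binw + 1] += rate / 5.0
            vals = rng_expr.poisson(lam)
            starts = np.arange(nb) * binw
            ends = np.minimum(starts + binw, len(seq))
            cov_frames.append(pd.DataFrame({
                "chromosome": chrom, "start": starts, "end": ends, "value": vals}))
        gio.write_bedgraph(pd.concat(cov_frames, ignore_index=True),
                           out(f"{strain}.coverage.bedgraph"))
        manifest[f"{strain}.coverage"] = out(f"{strain}.coverage.bedgraph")

        # repeats (mobile elements) as BED with class in the name column
        mes = pair.truth.mobile_elements[pair.truth.mobile_elements.strain == strain]
        gio.write_bed(mes.rename(columns={"class": "name"})[
            ["chromosome", "start", "end", "name"]].sort_values(
                ["chromosome", "start"]), out(f"{strain}.repeats.bed"))
        manifest[f"{strain}.repeats"] = out(f"{strain}.repeats.bed")

        # Hi-C triplets per chromosome, distance decay + intra-insertion boost
        for chrom, seq in seqs.items():
            nb = max(2, len(seq) // cfg.hic_bin_size)
            i, j = np.meshgrid(np.arange(nb), np.arange(nb), indexing="ij")
            lam = 200.0 / (1.0 + np.abs(i - j))
            in_ins = np.zeros(nb, dtype=bool)
            for _, ins in ins_s[ins_s.chromosome == chrom].iterrows():
                b0 = -(-ins.start // cfg.hic_bin_size)  # first bin fully inside
                b1 = ins.end // cfg.hic_bin_size
                in_ins[b0:b1] = True
            boost = np.outer(in_ins, in_ins) & (i != j)
            lam = np.where(boost, lam * cfg.hic_compaction, lam)
            upper = np.triu(rng_hic.poisson(lam))
            mat = upper + np.triu(upper, 1).T
            gio.write_hic_triplets(mat, cfg.hic_bin_size, chrom,
                                   out(f"{strain}.hic.{chrom}.tsv"))
            manifest[f"{strain}.hic.{chrom}"] = out(f"{strain}.hic.{chrom}.tsv")

    # ground-truth tables (headers included; these are for evaluation only)
    pair.truth.insertions.to_csv(out("truth.insertions.tsv"), sep="\t", index=False)
    pair.truth.genes.to_csv(out("truth.genes.tsv"), sep="\t", index=False)
    pair.truth.mobile_elements.to_csv(out("truth.mobile_elements.tsv"), sep="\t", index=False)
    pair.truth.duplication_links.to_csv(out("truth.duplication_links.tsv"), sep="\t", index=False)
    manifest["truth.insertions"] = out("truth.insertions.tsv")
    manifest["truth.genes"] = out("truth.genes.tsv")
    return manifest
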