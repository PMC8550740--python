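"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the design of a countrywide whitefly barcoding
survey: a reference panel of species-structured 651-nt mtCO1 barcodes
(inter-species divergence ~8%, within-species ~1%), NUMT artefacts carrying
in-window indels or premature stop codons, and field samples of three flies
per host plant with a known probability of containing a species mixture
(default 0.4, matching the ~40% typically observed).

Species sequences descend from a shipped synthetic seed ORF: each species
receives half the target pairwise divergence in substitutions at mutually
disjoint sites, so every species pair differs at approximately
``inter_divergence * 651`` sites. Substitutions never create an in-frame
stop codon, and within-species (query) substitutions are synonymous-only so
that clean queries can never trip the conserved-amino-acid screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import qc
from .seq_io import CollectionRecord, GeneticCode, INVERT_MITO_CODE, read_fasta

REGIONS = ("central", "northern", "eastern", "western")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_species: int = 6
    inter_divergence: float = 0.08
    intra_divergence: float = 0.01
    numt_indel_p: float = 0.5
    numt_stop_p: float = 0.5
    n_samples: int = 300
    flies_per_sample: int = 3
    mixing_p: float = 0.4
    host_profiles: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mixing_p <= 1.0:
            raise ValueError("mixing_p must lie in [0, 1]")
        for sp, profile in self.host_profiles.items():
            if abs(sum(profile.values()) - 1.0) > 1e-9:
                raise ValueError(f"host profile for {sp} does not sum to 1")


def load_seed_orf() -> str:
    """The shipped synthetic 651-nt ORF used as the ancestral barcode."""
    path = resources.files("coidiv") / "data" / "seed_orf.fasta"
    return read_fasta(str(path))[0].nt


def _substitute(
    nt: str,
    n_subs: int,
    rng: np.random.Generator,
    code: GeneticCode = INVERT_MITO_CODE,
    forbidden_sites: set[int] | None = None,
    synonymous_only: bool = False,
    max_tries: int = 10000,
) -> tuple[str, set[int]]:
    """Place exactly n_subs substitutions; never create a stop codon.

    Sites are drawn uniformly; a draw is rejected if the site was already
    used (here or in `forbidden_sites`), if every alternative base would
    create a stop, or — under synonymous_only — change the amino acid.
    """
    seq = list(nt)
    used: set[int] = set()
    forbidden = forbidden_sites or set()
    tries = 0
    while len(used) < n_subs:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_subs} substitutions (placed {len(used)})"
            )
        site = int(rng.integers(0, len(seq)))
        if site in used or site in forbidden:
            continue
        codon_i = site // 3
        codon = seq[3 * codon_i : 3 * codon_i + 3]
        pos_in_codon = site % 3
        old_aa = code.forward["".join(codon)]
        options = []
        for base in "ACGT":
            if base == seq[site]:
                continue
            trial = codon.copy()
            trial[pos_in_codon] = base
            tcodon = "".join(trial)
            if tcodon in code.stops:
                continue
            if synonymous_only and code.forward[tcodon] != old_aa:
                continue
            options.append(base)
        if not options:
            continue
        seq[site] = options[int(rng.integers(0, len(options)))]
        used.add(site)
    return "".join(seq), used


def simulate_panel(
    config: SimulationConfig,
    seed_sequence: str | None = None,
    species_names: list[str] | None = None,
    hlggs: list[str] | None = None,
) -> tuple[qc.ReferencePanel, list[tuple[str, str, str, str]]]:
    """Generate a species-structured reference panel from the seed ORF.

    Each species receives round(inter_divergence * L / 2) substitutions at
    sites disjoint from every other species, so realized pairwise
    p-distances sit within 1% of the target. Returns the built panel plus
    the raw (id, species, hlgg, nt) tuples.
    """
    seed_nt = seed_sequence if seed_sequence is not None else load_seed_orf()
    from .seq_io import translate

    _pep, stops = translate(seed_nt, 0)
    if stops:
        raise ValueError("seed sequence must encode an open reading frame")
    n = config.n_species
    if species_names is None:
        species_names = [f"SSA{i + 1}" for i in range(n)]
    if hlggs is None:
        hlggs = ["SSA"] * n
    if not (len(species_names) == len(hlggs) == n):
        raise ValueError("species_names/hlggs must match n_species")

    rng = np.random.default_rng(config.seed)
    k = round(config.inter_divergence * len(seed_nt) / 2)
    used_sites: set[int] = set()
    refs: list[tuple[str, str, str, str]] = []
    for name, hlgg in zip(species_names, hlggs):
        nt, sites = _substitute(seed_nt, k, rng, forbidden_sites=used_sites)
        used_sites |= sites
        refs.append((f"REF_{name.replace(' ', '_')}", name, hlgg, nt))

    from .distances import p_distance

    for i in range(n):
        for j in range(i + 1, n):
            p, _ = p_distance(refs[i][3], refs[j][3])
            if abs(p - config.inter_divergence) > 0.01:
                raise RuntimeError(
                    f"realized divergence {p:.4f} off target {config.inter_divergence}"
                )
    panel = qc.build_panel(refs, window_anchor=refs[0][0])
    return panel, refs


def simulate_queries(
    panel: qc.ReferencePanel,
    per_species_n: int,
    intra_divergence: float,
    seed: int,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Clean within-species queries: synonymous-only substitutions.

    Each query carries 0..round(intra * 651) synonymous substitutions from
    its species reference. Returns (id -> 651-nt barcode, truth table with
    columns seq_id/species/n_subs).
    """
    rng = np.random.default_rng(seed)
    max_subs = round(intra_divergence * qc.WINDOW_NT)
    queries: dict[str, str] = {}
    rows = []
    i = 0
    for entry in panel.entries:
        for _ in range(per_species_n):
            n_subs = int(rng.integers(0, max_subs + 1)) if max_subs else 0
            nt, _sites = _substitute(
                entry.window_nt, n_subs, rng, synonymous_only=True
            )
            sid = f"Q{i:04d}"
            queries[sid] = nt
            rows.append({"seq_id": sid, "species": entry.species, "n_subs": n_subs})
            i += 1
    return queries, pd.DataFrame(rows, columns=["seq_id", "species", "n_subs"])


def simulate_numts(
    panel: qc.ReferencePanel,
    n: int,
    indel_p: float,
    stop_p: float,
    seed: int,
) -> tuple[dict[str, str], pd.DataFrame]:
    """NUMT-like artefacts: in-window indels and/or premature stop codons.

    Every output carries at least one planted defect; the truth table
    records the defect category ('indel' or 'premature_stop') and its
    0-based window position.
    """
    if indel_p + stop_p <= 0:
        raise ValueError("indel_p + stop_p must be positive")
    rng = np.random.default_rng(seed)
    p_indel = indel_p / (indel_p + stop_p)
    numts: dict[str, str] = {}
    rows = []
    for i in range(n):
        entry = panel.entries[int(rng.integers(0, len(panel.entries)))]
        nt = entry.window_nt
        if rng.random() < p_indel:
            # 1-2 nt indel well inside the window so it cannot read as an end gap
            site = int(rng.integers(20, len(nt) - 20))
            width = int(rng.integers(1, 3))
            if rng.random() < 0.5:
                mutated = nt[:site] + nt[site + width :]
            else:
                mutated = nt[:site] + nt[site : site + width] + nt[site:]
            defect, pos = "indel", site
        else:
            codon_i = int(rng.integers(1, qc.WINDOW_AA - 1))
            stop = ("TAA", "TAG")[int(rng.integers(0, 2))]
            mutated = nt[: 3 * codon_i] + stop + nt[3 * codon_i + 3 :]
            defect, pos = "premature_stop", codon_i
        sid = f"NUMT{i:04d}"
        numts[sid] = mutated
        rows.append(
            {"seq_id": sid, "species": entry.species, "defect": defect, "position": pos}
        )
    return numts, pd.DataFrame(rows, columns=["seq_id", "species", "defect", "position"])


def simulate_survey(
    panel: qc.ReferencePanel,
    config: SimulationConfig,
) -> tuple[list[CollectionRecord], dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Field survey: n_samples host-site collections of flies_per_sample flies.

    With probability mixing_p a sample's flies span >= 2 species (enforced
    exactly, so the realized mixed fraction is Binomial(n_samples,
    mixing_p)/n_samples). Host choice follows the primary species'
    host-preference profile. Returns (records, fly barcodes, per-fly truth
    table, true host x species count matrix).
    """
    species = [e.species for e in panel.entries]
    for sp in species:
        if sp not in config.host_profiles:
            raise ValueError(f"no host profile for species {sp}")
    hosts = sorted({h for prof in config.host_profiles.values() for h in prof})
    by_species = {e.species: e for e in panel.entries}
    rng = np.random.default_rng(config.seed + 1)
    max_subs = round(config.intra_divergence * qc.WINDOW_NT)

    records: list[CollectionRecord] = []
    barcodes: dict[str, str] = {}
    rows = []
    truth = pd.DataFrame(0, index=hosts, columns=species, dtype=int)
    for s in range(config.n_samples):
        primary = species[int(rng.integers(0, len(species)))]
        profile = config.host_profiles[primary]
        host_names = list(profile)
        host = host_names[
            int(rng.choice(len(host_names), p=[profile[h] for h in host_names]))
        ]
        mixed = bool(rng.random() < config.mixing_p)
        fly_species = [primary] * config.flies_per_sample
        if mixed:
            others = [sp for sp in species if sp != primary]
            # at least one fly from a different species
            n_other = 1 + int(rng.integers(0, config.flies_per_sample - 1))
            for j in range(1, n_other + 1):
                fly_species[-j] = others[int(rng.integers(0, len(others)))]
        sample_id = f"S{s:04d}"
        fly_ids = []
        for j, sp in enumerate(fly_species):
            fid = f"{sample_id}_F{j}"
            n_subs = int(rng.integers(0, max_subs + 1)) if max_subs else 0
            nt, _ = _substitute(
                by_species[sp].window_nt, n_subs, rng, synonymous_only=True
            )
            barcodes[fid] = nt
            fly_ids.append(fid)
            truth.loc[host, sp] += 1
            rows.append(
                {"seq_id": fid, "sample_id": sample_id, "host": host,
                 "species": sp, "mixed_sample": mixed}
            )
        records.append(
            CollectionRecord(
                sample_id=sample_id,
                host_scientific=host,
                host_common="",
                host_family="Unknown",
                region=REGIONS[int(rng.integers(0, len(REGIONS)))],
                whitefly_ids=fly_ids,
            )
        )
    truth_flies = pd.DataFrame(
        rows, columns=["seq_id", "sample_id", "host", "species", "mixed_sample"]
    )
    return records, barcodes, truth_flies, truth


def simulate_block_matrix(
    n_blocks: int = 4,
    hosts_per_block: int = 4,
    species_per_block: int = 3,
    lam_in: float = 20.0,
    lam_out: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Planted-block host x species count matrix for clustering recovery.

    Each block of hosts concentrates its counts (Poisson(lam_in)) on its own
    block of species, with sparse background counts (Poisson(lam_out))
    elsewhere — the idealized form of specialist host-preference structure.
    """
    rng = np.random.default_rng(seed)
    nh, ns = n_blocks * hosts_per_block, n_blocks * species_per_block
    m = rng.poisson(lam_out, size=(nh, ns)).astype(int)
    for b in range(n_blocks):
        rows = slice(b * hosts_per_block, (b + 1) * hosts_per_block)
        cols = slice(b * species_per_block, (b + 1) * species_per_block)
        m[rows, cols] = rng.poisson(lam_in, size=(hosts_per_block, species_per_block))
    return pd.DataFrame(
        m,
        index=[f"host{i:02d}" for i in range(nh)],
        columns=[f"sp{j:02d}" for j in range(ns)],
    )


def default_host_profiles(species: list[str], n_hosts: int = 8,
                          specialist_weight: float = 0.8) -> dict[str, dict[str, float]]:
    """Simple specialist-vs-polyphagous preference structure.

    Each species concentrates `specialist_weight` of its probability on its
    own preferred host and spreads the rest uniformly over the other hosts.
    """
    hosts = [f"host{h:02d}" for h in range(n_hosts)]
    profiles = {}
    for i, sp in enumerate(species):
        pref = hosts[i % n_hosts]
        rest = (1.0 - specialist_weight) / (n_hosts - 1)
        profiles[sp] = {h: (specialist_weight if h == pref else rest) for h in hosts}
    return profiles
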