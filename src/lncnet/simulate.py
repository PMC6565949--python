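"""Seeded synthetic fixtures with the statistical structure the analysis assumes.

The generator emulates a small bulk RNA-seq experiment — two groups of three
biological replicates by default — at the level of per-transcript read counts.
Counts are negative-binomial around log-normal baseline means, a configurable
fraction of transcripts is planted as differentially expressed at a chosen
fold change, and a configurable number of lncRNA–mRNA pairs is planted with
near-perfect Pearson correlation so the downstream network stage has true
edges to recover.  Everything planted is recorded in a :class:`PlantedTruth`
object so recovery can be scored exactly.

With only six samples an unconditioned pair of count vectors essentially
never reaches |r| >= 0.95, so planted pairs are constructed, not sampled:
both members derive from one latent per-sample profile (the lncRNA's planted
group means with small bounded jitter) on the library-proportion scale, the
mRNA as a proportional transform (positive pairs) or range-midpoint
reflection (negative pairs) of that latent profile.  The construction is
verified empirically — on both the raw-count and the depth-normalised scale
— and regenerated when it falls below target.  See the methods note for why
each of these choices is forced at this sample size.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio

#: dispersion below this is treated as the Poisson limit
_POISSON_EPS = 1e-6


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic experiment.

    Defaults mirror a 3-vs-3 bulk design with a modest transcriptome slice:
    20 lncRNAs and 100 mRNAs, 20% of transcripts differentially expressed at
    4-fold, and five lncRNA–mRNA pairs planted at |r| >= 0.99 (comfortably
    above the 0.95 edge cutoff the network stage applies).
    """

    n_per_group: int = 3
    n_lncrna: int = 20
    n_mrna: int = 100
    frac_de: float = 0.2
    planted_fc: float = 4.0
    n_planted_pairs: int = 5
    planted_r: float = 0.99
    nb_dispersion: float = 0.02
    mean_log_expression: float = 5.0
    #: stdev of the log-normal baseline-mean distribution
    sd_log_expression: float = 1.0
    #: fraction of lncRNAs deliberately violating the candidate filters
    lncrna_fail_fraction: float = 0.0
    #: fraction of mRNAs placed within 10 kb of a lncRNA (cis-call exercise)
    cis_fraction: float = 0.1
    #: bound of the multiplicative noise on planted-pair coupling
    pair_noise: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_lncrna < 0 or self.n_mrna < 0:
            raise ValueError("transcript counts must be nonnegative")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if self.planted_fc < 1.0:
            raise ValueError("planted_fc must be >= 1")
        if not 0.0 <= self.planted_r <= 1.0:
            raise ValueError("planted_r must be in [0, 1]")
        if self.n_planted_pairs < 0:
            raise ValueError("n_planted_pairs must be >= 0")
        if not 0.0 <= self.lncrna_fail_fraction <= 1.0:
            raise ValueError("lncrna_fail_fraction must be in [0, 1]")
        if not 0.0 <= self.cis_fraction <= 1.0:
            raise ValueError("cis_fraction must be in [0, 1]")
        if self.n_planted_pairs > min(self.n_lncrna, self.n_mrna):
            raise ValueError("n_planted_pairs exceeds available transcripts")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PlantedTruth:
    """Record of everything the generator planted.

    ``de_transcripts`` has columns (transcript_id, direction, fold_change);
    ``correlated_pairs`` has columns (lncrna_id, mrna_id, sign).
    """

    de_transcripts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["transcript_id", "direction", "fold_change"]
        )
    )
    correlated_pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["lncrna_id", "mrna_id", "sign"])
    )


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Lay out synthetic transcript loci on a handful of chromosomes.

    Transcripts are tiled left to right with >40 kb gaps so that nothing is
    in cis range of anything else by accident; a ``cis_fraction`` of mRNAs is
    then re-placed a couple of kb downstream of a lncRNA so the 10-kb window
    logic has true positives to find.  By default every lncRNA passes the
    candidate filters (length > 200 nt, > 2 exons, all coding flags false);
    ``lncrna_fail_fraction`` plants deliberate violations for negative tests.
    """
    n_total = config.n_lncrna + config.n_mrna
    if n_total == 0:
        raise ValueError("at least one transcript must be requested")
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i}" for i in range(1, 6)]

    records = []
    cursor = {c: 10_000 for c in chroms}
    gap = 50_000

    n_fail = int(round(config.lncrna_fail_fraction * config.n_lncrna))
    for i in range(config.n_lncrna):
        chrom = chroms[i % len(chroms)]
        span = int(rng.integers(800, 3000))
        exonic_length = max(201, int(span * 0.7))
        exon_count = int(rng.integers(3, 6))
        flags = (False, False, False)
        if i < n_fail:  # cycle through the three ways to fail the filter
            mode = i % 3
            if mode == 0:
                exonic_length = int(rng.integers(50, 201))  # <= 200 nt
            elif mode == 1:
                exon_count = int(rng.integers(1, 3))  # 1-2 exons
            else:
                flags = (False, False, True)  # one coding verdict
        start = cursor[chrom]
        records.append(
            {
                "transcript_id": f"lnc{i:04d}",
                "biotype": "lncRNA_candidate",
                "chrom": chrom,
                "start": start,
                "end": start + span,
                "strand": "+" if rng.random() < 0.5 else "-",
                "exonic_length": exonic_length,
                "exon_count": exon_count,
                "flag_cpc": flags[0],
                "flag_cnci": flags[1],
                "flag_pfam": flags[2],
            }
        )
        cursor[chrom] = start + span + gap

    n_cis = int(round(config.cis_fraction * config.n_mrna))
    cis_partners = (
        rng.choice(config.n_lncrna, size=n_cis, replace=True)
        if config.n_lncrna and n_cis
        else np.array([], dtype=int)
    )
    for j in range(config.n_mrna):
        span = int(rng.integers(2000, 20000))
        if j < len(cis_partners):
            lnc = records[int(cis_partners[j])]
            chrom = lnc["chrom"]
            start = lnc["end"] + int(rng.integers(500, 8000))  # inside 10 kb
            cursor[chrom] = max(cursor[chrom], start + span + gap)
        else:
            chrom = chroms[j % len(chroms)]
            start = cursor[chrom]
            cursor[chrom] = start + span + gap
        records.append(
            {
                "transcript_id": f"mrna{j:04d}",
                "biotype": "coding",
                "chrom": chrom,
                "start": start,
                "end": start + span,
                "strand": "+" if rng.random() < 0.5 else "-",
                "exonic_length": int(rng.integers(500, 4000)),
                "exon_count": int(rng.integers(2, 15)),
                "flag_cpc": True,
                "flag_cnci": True,
                "flag_pfam": True,
            }
        )
    return pd.DataFrame.from_records(records, columns=lio.ANNOTATION_COLUMNS)


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws parameterised by mean and dispersion alpha.

    Var = mu + alpha * mu^2; alpha below ``_POISSON_EPS`` uses the Poisson
    limit directly to dodge overflow in the size parameter.
    """
    mu = np.asarray(mu, dtype=float)
    if dispersion < _POISSON_EPS:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_counts(
    config: SimulationConfig, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Draw the count matrix and plant DE transcripts and correlated pairs.

    Returns the transcript × sample integer matrix (samples named
    ``ctrl1..ctrlN, case1..caseN``) and the :class:`PlantedTruth` record.
    """
    if annotation.empty:
        raise ValueError("annotation is empty")
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be > 0")
    rng = np.random.default_rng(config.seed + 1)

    ids = annotation["transcript_id"].to_numpy()
    biotype = annotation.set_index("transcript_id")["biotype"]
    lnc_ids = [t for t in ids if biotype[t] == "lncRNA_candidate"]
    mrna_ids = [t for t in ids if biotype[t] != "lncRNA_candidate"]
    n = config.n_per_group
    samples = [f"ctrl{i + 1}" for i in range(n)] + [f"case{i + 1}" for i in range(n)]

    # log-normal baselines, clipped at +/-2 sigma: with only ~10^2 transcripts
    # sharing a library, an unclipped tail draw would dominate the column sums
    # and induce spurious composition shifts no real 20k-gene library shows
    m, s = config.mean_log_expression, config.sd_log_expression
    baseline = np.exp(
        np.clip(rng.normal(m, s, size=len(ids)), m - 2 * s, m + 2 * s)
    )
    baseline = pd.Series(baseline, index=ids)

    # --- choose planted pairs (lncRNA side from lncRNAs, mRNA side from coding)
    if config.n_planted_pairs > min(len(lnc_ids), len(mrna_ids)):
        raise ValueError("not enough transcripts of each biotype for planted pairs")
    pair_lnc = list(
        rng.choice(lnc_ids, size=config.n_planted_pairs, replace=False)
    ) if config.n_planted_pairs else []
    pair_mrna = list(
        rng.choice(mrna_ids, size=config.n_planted_pairs, replace=False)
    ) if config.n_planted_pairs else []
    pair_sign = ["positive" if rng.random() < 0.5 else "negative" for _ in pair_lnc]
    derived = set(pair_mrna)

    # --- choose planted DE transcripts.  Pair members are part of the DE set:
    # the network stage only sees DE-filtered transcripts, so a planted edge
    # must sit between transcripts that are themselves differentially
    # expressed — the across-group shift also supplies the expression spread
    # the coupling relies on.
    n_de = int(round(config.frac_de * len(ids)))
    de_ids = list(pair_lnc)
    free = [t for t in ids if t not in set(pair_lnc) | derived]
    extra = max(0, n_de - len(de_ids))
    if extra:
        de_ids += list(rng.choice(free, size=min(extra, len(free)), replace=False))
    # directions balanced exactly half-and-half (shuffled): in a slice of
    # ~10^2 transcripts an excess of one direction shifts the column sums
    # group-wise, a composition artifact a full-transcriptome library with a
    # small DE fraction does not exhibit
    dirs = ["up", "down"] * (len(de_ids) // 2 + 1)
    de_direction = dict(zip(de_ids, rng.permutation(dirs[: len(de_ids)])))
    # the coupled mRNA mirrors its partner's group shift (flipped for
    # negative pairs), so both pair members are planted DE; fixing the
    # direction now lets the placeholder draws below carry the right group
    # structure, keeping library sizes consistent with the final matrix
    for lnc_id, mrna_id, sign in zip(pair_lnc, pair_mrna, pair_sign):
        lnc_dir = de_direction[lnc_id]
        de_ids.append(mrna_id)
        de_direction[mrna_id] = (
            lnc_dir if sign == "positive" else ("down" if lnc_dir == "up" else "up")
        )

    # planted effects sit at or above the median baseline: a 4-fold shift on
    # a transcript at the Poisson noise floor is undetectable at n=3 and
    # would say nothing about the pipeline
    for t in set(de_ids) | derived | set(pair_lnc):
        baseline[t] = max(baseline[t], np.exp(m))
    # pair members sit higher still: a near-perfect empirical correlation is
    # only observable when integer counting noise is far below the planted
    # jitter, i.e. for abundant transcripts even in their low-expression group
    for t in derived | set(pair_lnc):
        baseline[t] = max(baseline[t], np.exp(m + s))

    def group_means(t: str) -> np.ndarray:
        mu = np.full(2 * n, baseline[t])
        if t in de_direction:
            if de_direction[t] == "up":
                mu[n:] *= config.planted_fc
            else:
                mu[n:] /= config.planted_fc
        return mu

    counts = pd.DataFrame(0, index=pd.Index(ids, name="transcript_id"), columns=samples, dtype=int)
    for t in ids:
        # pair members get an independent placeholder draw here so library
        # sizes are defined; the coupling below overwrites them
        counts.loc[t] = _nb_draw(rng, group_means(t), config.nb_dispersion)

    # two passes: the second re-plants against the library sizes the first
    # pass produced, so the normalised-scale coupling refers to the columns
    # sums of the emitted matrix, not of the placeholder draws
    for _ in range(2):
        lib = counts.sum(axis=0).to_numpy(dtype=float)
        for lnc_id, mrna_id, sign in zip(pair_lnc, pair_mrna, pair_sign):
            x, y = _plant_pair(
                rng,
                mu_lnc=group_means(lnc_id),
                mu_mrna=group_means(mrna_id),
                lib=lib,
                sign=sign,
                min_abs_r=config.planted_r,
                noise=config.pair_noise,
            )
            counts.loc[lnc_id] = x
            counts.loc[mrna_id] = y

    truth = PlantedTruth(
        de_transcripts=pd.DataFrame(
            {
                "transcript_id": de_ids,
                "direction": [de_direction[t] for t in de_ids],
                "fold_change": config.planted_fc,
            },
            columns=["transcript_id", "direction", "fold_change"],
        ),
        correlated_pairs=pd.DataFrame(
            {"lncrna_id": pair_lnc, "mrna_id": pair_mrna, "sign": pair_sign},
            columns=["lncrna_id", "mrna_id", "sign"],
        ),
    )
    return counts, truth


def _plant_pair(
    rng: np.random.Generator,
    mu_lnc: np.ndarray,
    mu_mrna: np.ndarray,
    lib: np.ndarray,
    sign: str,
    min_abs_r: float,
    noise: float,
    max_tries: int = 200,
    count_floor_r: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Count profiles of one planted pair, |r| enforced on both scales.

    Both members are driven by one latent profile — the lncRNA's planted
    per-sample means with small bounded multiplicative jitter — so the pair
    is tightly coupled by construction (a planted near-perfect pair is,
    by definition, a jointly low-noise pair; its members do not carry the
    full negative-binomial dispersion of the independent transcripts).
    The coupling acts on library proportions, the scale the pipeline's
    depth normalisation recovers, so the correlation survives RPKM:
    positive pairs are a proportional transform of the latent profile,
    negative pairs its reflection about the range midpoint, mapped back to
    counts via ``lib``.  Jitter is regenerated (shrinking on late attempts)
    until the rounded counts reach |r| >= min_abs_r on the normalised
    scale and |r| >= count_floor_r on the raw-count scale; the closest
    attempt is kept if the targets are never met.
    """
    zn = mu_lnc / lib  # latent normalised profile, group structure included
    if np.ptp(zn) == 0:
        # no planted group shift (fold change 1): give the latent profile
        # its own per-sample spread so the pair still has something to share
        zn = zn * np.exp(rng.normal(0.0, 0.5, size=zn.size))
    best = None
    for attempt in range(max_tries):
        damp = 0.5 ** (attempt // 20)
        # the per-sample jitter is shared by both members, with only a small
        # independent residual on top: under an exact permutation test the
        # group-preserving shuffles of a two-level profile tie the observed
        # |r| unless the within-group ordering itself carries the coupling
        eta = rng.uniform(-noise * damp, noise * damp, size=zn.size)
        # the pair's coupling must be visible WITHIN groups too — a shuffling
        # null cannot distinguish a purely two-level pair from group
        # structure alone — so reject jitter draws whose within-group spread
        # collapses below half the nominal bound
        half = zn.size // 2
        if half >= 2 and min(np.ptp(eta[:half]), np.ptp(eta[half:])) < noise * damp * 0.5:
            continue
        eps_x = rng.uniform(-noise * damp, noise * damp, size=zn.size) * 0.1
        eps_y = rng.uniform(-noise * damp, noise * damp, size=zn.size) * 0.1
        ln = zn * (1.0 + eta)
        xn = ln * (1.0 + eps_x)
        wn = ((ln.max() + ln.min()) - ln) if sign == "negative" else ln
        scale = mu_mrna.mean() / max(np.mean(wn * lib), 1e-12)
        yn = scale * wn * (1.0 + eps_y)
        x = np.maximum(np.rint(xn * lib), 0).astype(int)
        y = np.maximum(np.rint(yn * lib), 0).astype(int)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r_norm = np.corrcoef(x / lib, y / lib)[0, 1]
        r_count = np.corrcoef(x, y)[0, 1]
        if abs(r_norm) >= min_abs_r and abs(r_count) >= count_floor_r:
            return x, y
        score = min(abs(r_norm), abs(r_count))
        if best is None or score > best[0]:
            best = (score, x, y)
    if best is None:  # degenerate means (all zero): emit minimal ramps
        ramp = np.arange(zn.size)
        return ramp + 1, (ramp + 1) * 2
    return best[1], best[2]


# ---------------------------------------------------------------------------
# fixture writing


def write_fixture(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    truth: PlantedTruth,
    directory: str | os.PathLike,
    config: SimulationConfig | None = None,
) -> dict:
    """Write the fixture to ``directory`` and return its manifest.

    Files: ``counts.tsv``, ``annotation.gtf`` + BED-like ``annotation.tsv``,
    ``truth_de.tsv``, ``truth_pairs.tsv``, ``manifest.yaml``.  The manifest
    records the config (seed included) and the sample→group map, so the
    fixture round-trips losslessly through :mod:`lncnet.io`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not os.access(directory, os.W_OK):
        raise PermissionError(f"{directory} is not writable")

    lio.write_counts(counts, directory / "counts.tsv")
    lio.write_gtf(annotation, directory / "annotation.gtf")
    lio.write_annotation_tsv(annotation, directory / "annotation.tsv")
    truth.de_transcripts.to_csv(directory / "truth_de.tsv", sep="\t", index=False)
    truth.correlated_pairs.to_csv(directory / "truth_pairs.tsv", sep="\t", index=False)

    groups = {
        s: ("control" if s.startswith("ctrl") else "case") for s in counts.columns
    }
    manifest = {
        "config": config.to_dict() if config is not None else None,
        "seed": config.seed if config is not None else None,
        "groups": groups,
        "files": {
            "counts": "counts.tsv",
            "annotation_gtf": "annotation.gtf",
            "annotation_tsv": "annotation.tsv",
            "truth_de": "truth_de.tsv",
            "truth_pairs": "truth_pairs.tsv",
        },
    }
    lio.write_manifest(manifest, directory / "manifest.yaml")
    return manifest


def simulate_fixture(
    config: SimulationConfig, directory: str | os.PathLike | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Convenience wrapper: annotation + counts (+ optional on-disk fixture)."""
    annotation = generate_annotation(config)
    counts, truth = generate_counts(config, annotation)
    if directory is not None:
        write_fixture(counts, annotation, truth, directory, config)
    return counts, annotation, truth
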