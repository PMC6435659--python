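"""Transcriptome-like synthetic FASTQ generation.

The generator emulates the three properties of real RNA-seq data that the
normalizer exploits:

* **non-uniform coverage** — reads are drawn from transcripts with
  log-normally distributed relative expression, so per-transcript (and
  hence per-k-mer) coverage varies over orders of magnitude;
* **position-dependent base qualities** — the per-position mean phred
  score declines along the read (as on Illumina machines), with gaussian
  spread, and an optional *low-quality-early* switch additionally lowers
  the qualities of reads that appear early in the file (the positional
  skew that makes read ordering matter for normalization);
* **quality-coupled errors** — each base is substituted with probability
  ``10^(-q/10)`` given its simulated phred score q, so low-quality reads
  carry the low-abundance erroneous k-mers that weighted normalization is
  designed to avoid.

Substitution errors only (no indels): the normalizer operates on exact
labels, and substitutions suffice to create novel low-abundance labels.

Randomness: one seed per run.  ``SeedSequence(seed)`` is split into two
documented child streams — child 0 for transcript synthesis, child 1 for
read sampling — so each stage is individually reproducible and the pair
composes deterministically.  Same seed => byte-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .io_fastq import Read, ReadPair, write_pairs, write_records
from .kmer_core import revcomp

__all__ = [
    "SimConfig",
    "simulate_transcripts",
    "generate_reads",
    "generate_pairs",
    "simulate_reads",
    "make_fixture",
    "build_fixture",
    "FIXTURE_NAMES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHUNK = 100_000  # reads per generation chunk (bounds temporary memory)


@dataclass(slots=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    Quality model: position p of every read has mean phred
    ``qual_mean_start + (qual_mean_end - qual_mean_start) * p/(L-1)`` with
    s.d. ``qual_sd``; with ``low_quality_early`` on, read i additionally
    receives a shift of ``-low_early_span * (n-1-i)/(n-1)`` so the
    earliest reads in the file are systematically worse.
    """

    seed: int = 0
    n_transcripts: int = 20
    transcript_len_range: tuple[int, int] = (500, 2000)
    expression_mu: float = 0.0
    expression_sigma: float = 1.0
    read_len: int = 76
    n_reads: int = 10_000
    paired: bool = False
    n_pairs: int = 0
    fragment_len_mean: float = 200.0
    fragment_len_sd: float = 30.0
    qual_mean_start: float = 37.0
    qual_mean_end: float = 30.0
    qual_sd: float = 3.0
    low_quality_early: bool = False
    low_early_span: float = 18.0
    errors: bool = True
    both_strands: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.transcript_len_range
        if self.n_transcripts < 1:
            raise ConfigError("n_transcripts must be >= 1")
        if lo < 1 or hi < lo:
            raise ConfigError(f"degenerate transcript length range ({lo}, {hi})")
        if self.read_len < 1:
            raise ConfigError("read_len must be >= 1")
        if self.read_len > lo:
            raise ConfigError(
                f"read_len {self.read_len} exceeds the shortest possible "
                f"transcript length {lo}"
            )
        n = self.n_pairs if self.paired else self.n_reads
        if n < 1:
            raise ConfigError("must request at least one read/pair")
        if self.expression_sigma < 0 or self.qual_sd < 0:
            raise ConfigError("spread parameters must be non-negative")
        if self.paired and self.fragment_len_mean < self.read_len:
            raise ConfigError("fragment_len_mean must be >= read_len")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_transcripts": self.n_transcripts,
            "transcript_len_range": list(self.transcript_len_range),
            "expression_mu": self.expression_mu,
            "expression_sigma": self.expression_sigma,
            "read_len": self.read_len,
            "n_reads": self.n_reads,
            "paired": self.paired,
            "n_pairs": self.n_pairs,
            "fragment_len_mean": self.fragment_len_mean,
            "fragment_len_sd": self.fragment_len_sd,
            "qual_mean_start": self.qual_mean_start,
            "qual_mean_end": self.qual_mean_end,
            "qual_sd": self.qual_sd,
            "low_quality_early": self.low_quality_early,
            "low_early_span": self.low_early_span,
            "errors": self.errors,
            "both_strands": self.both_strands,
        }


def _streams(config: SimConfig) -> tuple[np.random.Generator, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def simulate_transcripts(config: SimConfig) -> list[tuple[str, str]]:
    """Uniform-random transcript sequences; deterministic given the seed."""
    rng, _ = _streams(config)
    lo, hi = config.transcript_len_range
    lens = rng.integers(lo, hi + 1, size=config.n_transcripts)
    out = []
    for i, L in enumerate(lens):
        seq = _BASES[rng.integers(0, 4, size=int(L))].tobytes().decode("ascii")
        out.append((f"tx{i}", seq))
    return out


def _quality_matrix(
    rng: np.random.Generator,
    config: SimConfig,
    n_total: int,
    first_index: int,
    count: int,
) -> np.ndarray:
    L = config.read_len
    pos = np.arange(L, dtype=np.float64)
    pos_mean = config.qual_mean_start + (
        config.qual_mean_end - config.qual_mean_start
    ) * (pos / max(L - 1, 1))
    q = pos_mean[None, :] + rng.normal(0.0, config.qual_sd, size=(count, L))
    if config.low_quality_early and n_total > 1:
        idx = np.arange(first_index, first_index + count, dtype=np.float64)
        shift = -config.low_early_span * (n_total - 1 - idx) / (n_total - 1)
        q += shift[:, None]
    return np.clip(np.rint(q), 2, 40).astype(np.int16)


def _apply_errors(
    rng: np.random.Generator, seqs: list[str], q: np.ndarray, enabled: bool
) -> list[str]:
    """Substitute bases with probability 10^(-q/10); returns mutated seqs."""
    if not enabled:
        return seqs
    perr = np.power(10.0, -q / 10.0)
    err = rng.random(q.shape) < perr
    n_err = int(err.sum())
    if n_err == 0:
        return seqs
    shifts = rng.integers(1, 4, size=n_err)
    pos_in_shifts = 0
    lut = {65: 0, 67: 1, 71: 2, 84: 3}
    rows = np.flatnonzero(err.any(axis=1))
    out = list(seqs)
    # shifts are consumed in row-major order over the error mask
    for r in rows:
        cols = np.flatnonzero(err[r])
        ba = bytearray(out[r], "ascii")
        for c in cols:
            code = lut[ba[c]]
            s = int(shifts[pos_in_shifts])
            pos_in_shifts += 1
            ba[c] = _BASES[(code + s) % 4]
        out[r] = ba.decode("ascii")
    return out


def _qual_strings(q: np.ndarray) -> list[str]:
    mat = (q + 33).astype(np.uint8)
    return [row.tobytes().decode("ascii") for row in mat]


def generate_reads(
    transcripts: Sequence[tuple[str, str]], config: SimConfig
) -> list[Read]:
    """Single-end reads in memory; see the module docstring for the model."""
    if not transcripts:
        raise ConfigError("transcript set is empty")
    _, rng = _streams(config)
    seqs = [s for _, s in transcripts]
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    if config.read_len > lens.min():
        raise ConfigError(
            f"read_len {config.read_len} exceeds shortest transcript ({lens.min()})"
        )
    n = config.n_reads
    L = config.read_len
    weights = rng.lognormal(config.expression_mu, config.expression_sigma, len(seqs))
    p = weights / weights.sum()
    t_idx = rng.choice(len(seqs), size=n, p=p)
    starts = rng.integers(0, lens[t_idx] - L + 1)
    strands = (
        rng.integers(0, 2, size=n) if config.both_strands else np.zeros(n, np.int64)
    )

    reads: list[Read] = []
    for c0 in range(0, n, _CHUNK):
        c1 = min(c0 + _CHUNK, n)
        q = _quality_matrix(rng, config, n, c0, c1 - c0)
        raw = []
        for i in range(c0, c1):
            s = seqs[t_idx[i]][starts[i] : starts[i] + L]
            raw.append(revcomp(s) if strands[i] else s)
        mutated = _apply_errors(rng, raw, q, config.errors)
        quals = _qual_strings(q)
        for j, i in enumerate(range(c0, c1)):
            reads.append(Read(id=f"read{i}", seq=mutated[j], qual=quals[j]))
    return reads


def generate_pairs(
    transcripts: Sequence[tuple[str, str]], config: SimConfig
) -> list[ReadPair]:
    """Inward-facing mate pairs from sampled fragments."""
    if not transcripts:
        raise ConfigError("transcript set is empty")
    if not config.paired or config.n_pairs < 1:
        raise ConfigError("config is not a paired configuration")
    _, rng = _streams(config)
    seqs = [s for _, s in transcripts]
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    n = config.n_pairs
    L = config.read_len
    weights = rng.lognormal(config.expression_mu, config.expression_sigma, len(seqs))
    p = weights / weights.sum()
    t_idx = rng.choice(len(seqs), size=n, p=p)
    flen = np.rint(
        rng.normal(config.fragment_len_mean, config.fragment_len_sd, size=n)
    ).astype(np.int64)
    flen = np.minimum(np.maximum(flen, L), lens[t_idx])
    starts = rng.integers(0, lens[t_idx] - flen + 1)

    pairs: list[ReadPair] = []
    for c0 in range(0, n, _CHUNK):
        c1 = min(c0 + _CHUNK, n)
        q_left = _quality_matrix(rng, config, n, c0, c1 - c0)
        q_right = _quality_matrix(rng, config, n, c0, c1 - c0)
        raw_l, raw_r = [], []
        for i in range(c0, c1):
            frag = seqs[t_idx[i]][starts[i] : starts[i] + flen[i]]
            raw_l.append(frag[:L])
            raw_r.append(revcomp(frag[-L:]))
        mut_l = _apply_errors(rng, raw_l, q_left, config.errors)
        mut_r = _apply_errors(rng, raw_r, q_right, config.errors)
        ql, qr = _qual_strings(q_left), _qual_strings(q_right)
        for j, i in enumerate(range(c0, c1)):
            pairs.append(
                ReadPair(
                    left=Read(id=f"frag{i}/1", seq=mut_l[j], qual=ql[j]),
                    right=Read(id=f"frag{i}/2", seq=mut_r[j], qual=qr[j]),
                    index=i,
                )
            )
    return pairs


def simulate_reads(
    transcripts: Sequence[tuple[str, str]],
    config: SimConfig,
    path,
    path2=None,
) -> None:
    """Generate reads (or pairs, when the config is paired) and write FASTQ."""
    if config.paired:
        if path2 is None:
            raise ConfigError("paired simulation needs two output paths")
        write_pairs(generate_pairs(transcripts, config), path, path2)
    else:
        write_records(generate_reads(transcripts, config), path)


# ---------------------------------------------------------------------
# Named, seed-pinned fixtures shared by the test suite.

#: the 4-read worked example: three copies of AAAAA plus one AAAAC, with
#: qualities chosen so qr = [0, 200, 115, 200]; analysed at k=3, b=2,
#: forward-strand labels
_TINY_READS = [
    Read(id="r0", seq="AAAAA", qual="!!!!!"),
    Read(id="r1", seq="AAAAA", qual="IIIII"),
    Read(id="r2", seq="AAAAA", qual="88888"),
    Read(id="r3", seq="AAAAC", qual="IIIII"),
]

_FIXTURE_CONFIGS: dict[str, SimConfig] = {
    "ordering-skew": SimConfig(
        seed=20190326,
        n_transcripts=12,
        transcript_len_range=(300, 900),
        expression_sigma=1.2,
        read_len=60,
        n_reads=4000,
        low_quality_early=True,
        low_early_span=18.0,
    ),
    "paired-small": SimConfig(
        seed=1093,
        n_transcripts=6,
        transcript_len_range=(400, 800),
        expression_sigma=1.0,
        read_len=50,
        paired=True,
        n_pairs=400,
        n_reads=1,
        fragment_len_mean=180.0,
        fragment_len_sd=25.0,
    ),
    "scale-1m": SimConfig(
        seed=761932,
        n_transcripts=150,
        transcript_len_range=(500, 3000),
        expression_sigma=1.0,
        read_len=76,
        n_reads=1_000_000,
    ),
}

#: normalization parameters each fixture is analysed with
FIXTURE_PARAMS: dict[str, dict] = {
    "tiny": {"k": 3, "b": 2.0, "canonical": False},
    "ordering-skew": {"k": 11, "b": 1.7, "canonical": True},
    "paired-small": {"k": 11, "b": 1.7, "canonical": True},
    "scale-1m": {"k": 22, "b": 1.7, "canonical": True},
}

FIXTURE_NAMES = ("tiny", "ordering-skew", "paired-small", "scale-1m")


def build_fixture(name: str):
    """In-memory fixture: returns (reads_or_pairs, params dict)."""
    if name == "tiny":
        return [replace(r) for r in _TINY_READS], dict(FIXTURE_PARAMS["tiny"])
    if name not in _FIXTURE_CONFIGS:
        raise ConfigError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    config = _FIXTURE_CONFIGS[name]
    transcripts = simulate_transcripts(config)
    data = (
        generate_pairs(transcripts, config)
        if config.paired
        else generate_reads(transcripts, config)
    )
    return data, dict(FIXTURE_PARAMS[name])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def make_fixture(name: str, outdir) -> dict:
    """Write a named fixture to ``outdir`` plus a YAML manifest; returns
    the manifest dict (config, analysis parameters, file digests)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data, params = build_fixture(name)
    files: list[Path] = []
    if data and isinstance(data[0], ReadPair):
        files = [outdir / f"{name}_1.fastq", outdir / f"{name}_2.fastq"]
        write_pairs(data, files[0], files[1])
    else:
        files = [outdir / f"{name}.fastq"]
        write_records(data, files[0])
    config = (
        _FIXTURE_CONFIGS[name].to_dict() if name in _FIXTURE_CONFIGS else None
    )
    manifest = {
        "name": name,
        "config": config,
        "params": params,
        "files": {f.name: _sha256(f) for f in files},
    }
    with open(outdir / f"{name}.manifest.yaml", "wt") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
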