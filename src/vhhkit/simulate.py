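"""Synthetic VHH repertoires and SAR datasets with known ground truth.

The repertoire generator emulates the statistical structure of camelid
VHH NGS repertoires at desk scale so that every analysis stage can be
exercised without external data:

* Hallmark motif mixture over positions 42/49/50/52 (the four field-wide
  most prevalent motifs FERF/FERG/VGLW/YQRL together make up 61% of
  sequences, plus minor motifs);
* motif-conditional CDR3 length (shifted negative binomial, minimum 3),
  with the FERG subset longest (mean 18.4) and the VGLW/YQRL subsets
  shortest (14.4/14.6), ALL mean 16.6;
* germline-linked non-canonical cysteines: with a motif-dependent
  probability (highest for FERG) a cysteine pair is written at position
  55 and at a uniformly random CDR3 position, for a marginal Cys-subset
  fraction of ~30%; Cys-carrying sequences have longer CDR3s (subset
  mean 19.0) without perturbing the per-motif subset means;
* Hallmark-coupled position 40: Gly-dominant (63.9%) except under the
  human-like VGLW motif, where Ser/Thr/Tyr/Asn dominate (51.2% Ser) --
  the coupling that places position 40 in one NMI cluster with the
  Hallmark positions.  Setting ``position40_coupling=False`` samples
  position 40 from the motif-independent marginal instead.

All randomness flows from ``cfg.seed``; identical configs give
byte-identical repertoires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import NumberedSequence, Residue, imgt_key, loop_position_keys
from .errors import ConfigError
from .germlines import base_scaffold
from .sar import AffinityRecord

AA_NO_CYS = tuple("ADEFGHIKLMNPQRSTVWY")  # background sampling avoids stray Cys

#: the rare-motif remainder; its Hallmark letters are drawn independently
#: from per-position pools (rejecting the named motifs), mimicking the long
#: tail of rare Hallmark combinations in real repertoires
OTHER = "OTHER"

# Named motifs cover the four field-wide dominant signatures (together 61%)
# plus the two rare signatures carried by characterized NKp30 binders.
DEFAULT_MOTIF_MIX = {
    "FERF": 0.21, "FERG": 0.17, "VGLW": 0.13, "YQRL": 0.10,
    "VEHG": 0.03, "FARS": 0.02, OTHER: 0.34,
}

DEFAULT_P_CYS = {
    "FERF": 0.28, "FERG": 0.62, "VGLW": 0.05, "YQRL": 0.22,
    "VEHG": 0.30, "FARS": 0.15, OTHER: 0.28,
}

DEFAULT_CDR3_MEANS = {
    "FERF": 16.3, "FERG": 18.4, "VGLW": 14.4, "YQRL": 14.6,
    "VEHG": 17.5, "FARS": 17.0, OTHER: 17.2,
}

#: per-position residue pools for the OTHER (rare-motif) remainder
DEFAULT_OTHER_POOLS = {
    42: {"F": 0.45, "V": 0.25, "Y": 0.20, "L": 0.10},
    49: {"E": 0.50, "G": 0.20, "Q": 0.18, "A": 0.12},
    50: {"R": 0.55, "L": 0.25, "H": 0.10, "K": 0.10},
    52: {"G": 0.28, "W": 0.22, "L": 0.20, "F": 0.15, "S": 0.15},
}

# Position-40 conditional distributions.  The mixture over the default
# motif mix reproduces the repertoire-wide marginal (Gly 63.9%, Ala 13.7%,
# Ser 10.6%); the human-like VGLW signature flips to Ser/Thr/Tyr/Asn
# (51.2% Ser), and rare-motif sequences carrying Val42 leap toward the
# same hydrogen-bonding residues.
POS40_BY_MOTIF = {
    "FERF": {"G": 0.85, "A": 0.06, "S": 0.04, "D": 0.03, "E": 0.02},
    "FERG": {"G": 0.68, "A": 0.12, "S": 0.02, "N": 0.09, "T": 0.09},
    "VGLW": {"S": 0.512, "T": 0.141, "Y": 0.109, "N": 0.100, "G": 0.08, "A": 0.058},
    "YQRL": {"G": 0.58, "A": 0.32, "S": 0.05, "D": 0.05},
    "VEHG": {"G": 0.78, "A": 0.10, "S": 0.04, "D": 0.08},
    "FARS": {"G": 0.70, "A": 0.15, "S": 0.04, "N": 0.11},
}
#: OTHER sequences condition position 40 on their sampled residue 42
POS40_OTHER_BY_42 = {
    "V": {"G": 0.45, "S": 0.22, "A": 0.15, "T": 0.10, "N": 0.08},
}
POS40_OTHER_DEFAULT = {"G": 0.79, "A": 0.17, "S": 0.01, "D": 0.02, "N": 0.01}


@dataclass
class RepertoireConfig:
    n_sequences: int = 2000
    seed: int = 0
    motif_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MOTIF_MIX))
    p_cys_given_motif: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_P_CYS))
    cdr3_mean_by_motif: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CDR3_MEANS))
    cdr3_mean_cys_subset: float = 19.0
    cdr3_dispersion: float = 8.0      # negative-binomial size parameter
    cdr3_min_length: int = 3
    position40_coupling: bool = True
    position40_by_motif: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in POS40_BY_MOTIF.items()}
    )
    position40_other_by_42: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in POS40_OTHER_BY_42.items()}
    )
    position40_default: Mapping[str, float] = field(
        default_factory=lambda: dict(POS40_OTHER_DEFAULT)
    )
    other_hallmark_pools: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OTHER_POOLS.items()}
    )
    point_mutation_rate: float = 0.01

    def __post_init__(self):
        if self.n_sequences <= 0:
            raise ConfigError("n_sequences must be positive")
        if abs(sum(self.motif_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("motif_mix must sum to 1")
        dists = [self.position40_default, *self.position40_by_motif.values(),
                 *self.position40_other_by_42.values(), *self.other_hallmark_pools.values()]
        for dist in dists:
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError("probability maps must sum to 1")
        for motif in self.motif_mix:
            if motif != OTHER and (len(motif) != 4 or not motif.isalpha()):
                raise ConfigError(f"bad motif {motif!r}")
            if motif not in self.p_cys_given_motif:
                raise ConfigError(f"p_cys_given_motif missing motif {motif}")
            if motif not in self.cdr3_mean_by_motif:
                raise ConfigError(f"cdr3_mean_by_motif missing motif {motif}")
        if any(m <= self.cdr3_min_length for m in self.cdr3_mean_by_motif.values()):
            raise ConfigError("CDR3 means must exceed the minimum length")

    @property
    def named_motifs(self) -> frozenset:
        return frozenset(m for m in self.motif_mix if m != OTHER)

    def cys_length_shift(self) -> float:
        """Within-motif CDR3-mean shift for Cys carriers.

        Solved so that each motif-subset mean stays at its configured value
        (carriers get ``+d*(1-p)``, non-carriers ``-d*p``) while the pooled
        Cys-subset mean hits ``cdr3_mean_cys_subset``.
        """
        w = {m: self.motif_mix[m] * self.p_cys_given_motif[m] for m in self.motif_mix}
        total = sum(w.values())
        if total == 0:
            return 0.0
        weighted_mean = sum(w[m] * self.cdr3_mean_by_motif[m] for m in w) / total
        denom = sum(w[m] * (1.0 - self.p_cys_given_motif[m]) for m in w) / total
        if denom == 0:
            return 0.0
        return (self.cdr3_mean_cys_subset - weighted_mean) / denom


@dataclass
class RepertoireTruth:
    """Per-sequence ground truth and realized global frequencies."""

    records: pd.DataFrame   # id, motif, cys, cdr3_length, position40
    motif_frequencies: dict
    cys_fraction: float

    def to_json(self, path) -> None:
        payload = {
            "motif_frequencies": self.motif_frequencies,
            "cys_fraction": self.cys_fraction,
            "records": self.records.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _sample(rng: np.random.Generator, dist: Mapping[str, float]) -> str:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _cdr3_length(rng: np.random.Generator, mean: float, r: float, minimum: int) -> int:
    mu = max(mean - minimum, 0.1)
    p = r / (r + mu)
    return minimum + int(rng.negative_binomial(r, p))


_HALLMARK_SLOTS = (42, 49, 50, 52)


def generate_repertoire(cfg: RepertoireConfig) -> tuple[list, RepertoireTruth]:
    """Sample a repertoire of fully annotated numbered sequences + truth."""
    rng = np.random.default_rng(cfg.seed)
    scaffold = base_scaffold()
    shift = cfg.cys_length_shift()
    protected = {23, 104, 118, 41, 40, 55, *_HALLMARK_SLOTS}

    marginal40 = _marginal_pos40(cfg)
    seqs = []
    rows = []
    for i in range(cfg.n_sequences):
        motif_class = _sample(rng, cfg.motif_mix)
        if motif_class == OTHER:
            while True:
                motif = "".join(
                    _sample(rng, cfg.other_hallmark_pools[p]) for p in _HALLMARK_SLOTS
                )
                if motif not in cfg.named_motifs:
                    break
        else:
            motif = motif_class
        has_cys = bool(rng.random() < cfg.p_cys_given_motif[motif_class])
        if not cfg.position40_coupling:
            pos40_dist = marginal40
        elif motif_class == OTHER:
            pos40_dist = cfg.position40_other_by_42.get(motif[0], cfg.position40_default)
        else:
            pos40_dist = cfg.position40_by_motif.get(motif_class, cfg.position40_default)
        pos40 = _sample(rng, pos40_dist)
        mean = cfg.cdr3_mean_by_motif[motif_class]
        p_c = cfg.p_cys_given_motif[motif_class]
        mean = mean + shift * (1.0 - p_c) if has_cys else mean - shift * p_c
        length = _cdr3_length(rng, mean, cfg.cdr3_dispersion, cfg.cdr3_min_length)

        table = dict(scaffold)
        for pos in range(105, 118):
            table.pop(pos, None)
        for slot, aa in zip(_HALLMARK_SLOTS, motif):
            table[slot] = aa
        table[40] = pos40
        table[55] = "C" if has_cys else table[55]

        cdr3_keys = loop_position_keys("cdr3", length)
        cdr3_res = [str(rng.choice(AA_NO_CYS)) for _ in range(length)]
        if has_cys and length:
            cdr3_res[int(rng.integers(length))] = "C"

        # background substitutions outside anchors and model-assigned sites
        for pos in sorted(table):
            if pos in protected:
                continue
            if rng.random() < cfg.point_mutation_rate:
                table[pos] = str(rng.choice(AA_NO_CYS))

        residues = [Residue(p, "", aa) for p, aa in table.items()]
        residues += [Residue(p, ins, aa) for (p, ins), aa in zip(cdr3_keys, cdr3_res)]
        residues.sort(key=lambda r: imgt_key(r.position, r.insertion))
        ns = NumberedSequence(f"synth{i:05d}", residues)
        seqs.append(ns)
        rows.append(
            {"id": ns.id, "motif": motif, "motif_class": motif_class, "cys": has_cys,
             "cdr3_length": length, "position40": pos40}
        )

    records = pd.DataFrame(rows)
    freqs = records["motif_class"].value_counts(normalize=True).to_dict()
    truth = RepertoireTruth(records, freqs, float(records["cys"].mean()))
    return seqs, truth


def _marginal_pos40(cfg: RepertoireConfig) -> dict:
    """Motif-independent position-40 distribution (coupling disabled)."""
    marginal: dict[str, float] = {}

    def _add(w: float, dist: Mapping[str, float]) -> None:
        for aa, p in dist.items():
            marginal[aa] = marginal.get(aa, 0.0) + w * p

    for motif, w in cfg.motif_mix.items():
        if motif == OTHER:
            pool42 = cfg.other_hallmark_pools[42]
            for aa42, p42 in pool42.items():
                _add(w * p42, cfg.position40_other_by_42.get(aa42, cfg.position40_default))
        else:
            _add(w, cfg.position40_by_motif.get(motif, cfg.position40_default))
    total = sum(marginal.values())
    return {aa: p / total for aa, p in marginal.items()}


# ---------------------------------------------------------------------------
# synthetic SAR tables


def generate_sar(
    effects: Mapping[str, float],
    n_variants: int = 24,
    noise_sigma: float = 0.1,
    seed: int = 0,
    parental_kd: float = 1.0,
    knockouts: frozenset | set = frozenset(),
    parental_id: str = "SYN-v0",
) -> tuple[list, list]:
    """Affinity table + mutation sets with known multiplicative effects.

    Each variant carries a random subset of the mutations; its KD is the
    parental KD times the product of its mutations' fold effects times
    lognormal noise.  Variants containing a knockout mutation are emitted
    as non-binders.  Returns ``(records, [(variant_id, mutation set)])``.
    """
    if any(e <= 0 for e in effects.values()):
        raise ConfigError("fold effects must be positive")
    rng = np.random.default_rng(seed)
    mutations = sorted(set(effects) | set(knockouts))
    if n_variants + 1 > 2 ** len(mutations):
        raise ConfigError("n_variants exceeds the number of distinct mutation subsets")

    records = [AffinityRecord(parental_id, parental_kd)]
    variant_sets = [(parental_id, frozenset())]
    seen = {frozenset()}
    i = 1
    while len(variant_sets) < n_variants + 1:
        subset = frozenset(m for m in mutations if rng.random() < 0.5)
        if subset in seen:
            continue
        seen.add(subset)
        vid = f"SYN-v{i}"
        i += 1
        if subset & set(knockouts):
            records.append(AffinityRecord(vid, None))
        else:
            kd = parental_kd
            for m in subset:
                kd *= effects[m]
            kd *= float(np.exp(rng.normal(0.0, noise_sigma)))
            records.append(AffinityRecord(vid, kd))
        variant_sets.append((vid, subset))
    return records, variant_sets
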