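"""Model parameters for a nonrecombining block of selected sites.

The model is the classical reversible two-allele scheme used in studies of
selection on codon usage: a haploid genome carries ``L`` completely linked
diallelic sites.  At each site the favored allele A1 mutates to the
deleterious allele A2 at rate ``u`` per generation and back at rate
``v = u / kappa``, where ``kappa`` is the mutational bias.  Carriers of A2
have fitness ``1 - s`` relative to A1 carriers and fitnesses multiply across
sites.  Drift is governed by a baseline variance effective population size
``N0`` in the absence of interference.

Scaled parameters follow the haploid convention: ``gamma0 = 2 N0 s`` and
``alpha0 = 2 N0 U`` with ``U = L u`` the total deleterious mutation rate per
genome.  The diploid mapping (replace N0 by 2N0 and s by the heterozygous
effect) is documented in the methods note but not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set for the nonrecombining-block model.

    Parameters
    ----------
    N0 : float
        Baseline effective population size (haploid individuals), >= 2.
    s : float
        Selection coefficient against the deleterious allele, >= 0.
    u : float
        Mutation rate A1 -> A2 per site per generation, > 0.
    kappa : float
        Mutational bias ``u / v``, > 0.  ``kappa = 1`` means no bias.
    L : int
        Number of selected sites, >= 1.
    """

    N0: float
    s: float
    u: float
    kappa: float
    L: int
    U: float = field(init=False)
    v: float = field(init=False)
    gamma0: float = field(init=False)
    alpha0: float = field(init=False)

    def __post_init__(self) -> None:
        if self.N0 < 2:
            raise ValueError(f"N0 must be >= 2, got {self.N0}")
        if self.s < 0:
            raise ValueError(f"s must be >= 0, got {self.s}")
        if self.u <= 0:
            raise ValueError(f"u must be > 0, got {self.u}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        object.__setattr__(self, "U", self.L * self.u)
        object.__setattr__(self, "v", self.u / self.kappa)
        object.__setattr__(self, "gamma0", 2.0 * self.N0 * self.s)
        object.__setattr__(self, "alpha0", 2.0 * self.N0 * self.U)

    @classmethod
    def from_gamma0(
        cls, N0: float, gamma0: float, u: float, kappa: float, L: int
    ) -> "ModelParams":
        """Construct from the scaled selection strength ``gamma0 = 2 N0 s``."""
        return cls(N0=N0, s=gamma0 / (2.0 * N0), u=u, kappa=kappa, L=L)

    def asdict(self) -> dict:
        return {
            "N0": self.N0,
            "s": self.s,
            "u": self.u,
            "kappa": self.kappa,
            "L": self.L,
            "U": self.U,
            "gamma0": self.gamma0,
            "alpha0": self.alpha0,
        }


@dataclass(frozen=True)
class FitnessVariances:
    """Fitness variances on the additive (per-generation) scale.

    ``Va`` is the additive genetic variance in relative fitness, ``Vg`` the
    genic variance obtained by summing single-site variances while ignoring
    linkage disequilibrium (so ``Va == Vg`` under the no-LD assumption used
    throughout the analytical machinery), and ``Vm`` the variance introduced
    per generation by new mutations.
    """

    Va: float
    Vg: float
    Vm: float

    def __post_init__(self) -> None:
        for name in ("Va", "Vg", "Vm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PartialNeutralityModel:
    """Two-class alternative model: a fraction of selected sites is strongly
    selected (diversity insensitive to interference), the rest neutral.

    Used to contrast the interference prediction for the ratio of selected to
    neutral diversity with the behavior expected if apparent selection is a
    mixture of strong constraint and neutrality.
    """

    Ps: float
    pi_strong: float
    pi_neut0: float
    Bprime: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.Ps <= 1.0:
            raise ValueError("Ps must lie in [0, 1]")
        if self.pi_strong < 0 or self.pi_neut0 < 0:
            raise ValueError("diversities must be >= 0")
        if not 0.0 < self.Bprime <= 1.0:
            raise ValueError("Bprime must lie in (0, 1]")
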