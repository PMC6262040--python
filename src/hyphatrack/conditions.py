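"""Reference cultivation-condition presets for the synthetic generator.

Each preset bundles the published single-cell growth characteristics of
*Streptomyces lividans* TK24 under one medium condition — germination
delay, hyphal growth unit, tip elongation rate and the matching
scattered-light (plate-culture) lag and specific growth rate — so that
simulation studies can be parameterized per condition with one call.

CM is the full complex medium (fastest growth, largest HGU); CAS/AA20/
AA08/AA04 are minimal media with decreasing amino-acid supplementation;
AA00 is unsupplemented minimal medium.  Where a condition's mean tip
elongation rate was not published directly, it is derived from the
identity v = mu * HGU (exponential mycelial growth arises from branching
at constant HGU, so the specific rate of total length equals mean tip
rate over HGU); tip-rate spread is scaled to keep the CM coefficient of
variation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .simulate import ScatterSignalParams, SimulationParams

MEDIA = ("CM", "CAS", "AA20", "AA08", "AA04", "AA00")


@dataclass(frozen=True)
class ConditionPreset:
    medium_id: str
    germ_delay_mean_h: float
    germ_delay_sd_h: float
    target_hgu_um: float
    tip_rate_mean_um_h: float
    tip_rate_sd_um_h: float
    mscc_mu_h: float            # specific growth rate, single-cell chambers
    mtpc_mu_h: float            # specific growth rate, plate culture
    mtpc_lag_h: float

    def simulation_params(self, **overrides) -> SimulationParams:
        params = SimulationParams(
            germ_delay_mean_h=self.germ_delay_mean_h,
            germ_delay_sd_h=self.germ_delay_sd_h,
            target_hgu_um=self.target_hgu_um,
            tip_rate_mean_um_h=self.tip_rate_mean_um_h,
            tip_rate_sd_um_h=self.tip_rate_sd_um_h,
        )
        return replace(params, **overrides) if overrides else params

    def scatter_params(self, **overrides) -> ScatterSignalParams:
        params = ScatterSignalParams(lag_h=self.mtpc_lag_h,
                                     mu_h=self.mtpc_mu_h)
        return replace(params, **overrides) if overrides else params


_CV = 6.1 / 14.1   # CM tip-rate coefficient of variation, reused below


def _derived(medium_id: str, germ_mean: float, germ_sd: float, hgu: float,
             mscc_mu: float, mtpc_mu: float, lag: float) -> ConditionPreset:
    v = mscc_mu * hgu
    return ConditionPreset(medium_id, germ_mean, germ_sd, hgu,
                           v, _CV * v, mscc_mu, mtpc_mu, lag)


#: Reference condition values.  CM is fully published; for CAS and AA04
#: the tip-rate fields are derived via v = mu * HGU, and the CAS
#: germination delay / lag are interpolated placeholders (published only
#: as "comparable to AA20, faster than AA04") — adequate for demo runs,
#: not used as recovery targets.
CONDITIONS: dict[str, ConditionPreset] = {
    "CM": ConditionPreset(
        medium_id="CM",
        germ_delay_mean_h=10.0, germ_delay_sd_h=2.4,
        target_hgu_um=28.7,
        tip_rate_mean_um_h=14.1, tip_rate_sd_um_h=6.1,
        mscc_mu_h=0.38, mtpc_mu_h=0.33, mtpc_lag_h=9.3,
    ),
    "CAS": _derived("CAS", 20.0, 3.0, 17.4, 0.27, 0.23, 15.0),
    "AA04": _derived("AA04", 33.5, 3.9, 14.3, 0.22, 0.17, 25.0),
}

#: Pooled fraction of spores that germinated across all media.
POOLED_GERMINATION_FRACTION = 0.3612
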