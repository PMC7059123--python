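"""In-silico versions of the voltage-clamp pH protocols used to
characterise ASIC1a kinetics.

Each builder assembles a single long waveform spanning all sweeps, so that
gate state carries over between sweeps exactly as in the recordings
(including the inter-sweep recovery intervals).  Alongside the waveform,
every sweep is annotated with analysis windows (control response, test
response, deactivation tail, ...) so that rate- and curve-extraction can be
applied mechanically to the simulated current.

Protocol timings follow the experimental conventions:

- activation series: a 3-s acidic test stimulus every 40 s from pH 7.4
  (fast solution exchange; opening and current-decay kinetics);
- deactivation: 120 ms at pH 6.0, then return to the recovery pH;
- steady-state activation curve: a 5-s test stimulus every 50 s;
- steady-state desensitization (SSD) curve: 8 s pH 6.0 (I1) / 40 s pH 7.4 /
  60 s conditioning pH / 8 s pH 6.0 (I2) / 42 s pH 7.4 per conditioning pH;
- SSD kinetics: 5 s pH 6.0 control, 40 s recovery, conditioning pH for a
  variable duration, 5 s pH 6.0 test;
- recovery kinetics: 10 s pH 6.0 (desensitising), recovery pH for a
  variable duration, 5 s pH 6.0 test.

All builders accept the solution-exchange time in ms (1 ms for excised
outside-out patches, 200 ms for whole cells); every pH transition is a short
linear ramp of that length, so waveforms are continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .waveforms import PHWaveform, make_constant, make_step

__all__ = ["SweepInfo", "Protocol", "protocol_library", "PROTOCOL_NAMES"]

PH_BASE = 7.4
PH_TEST = 6.0


@dataclass(frozen=True)
class SweepInfo:
    """Annotation of one sweep within a multi-sweep protocol waveform."""

    value: float  # the varied pH of this sweep (test / conditioning / recovery)
    duration: float | None  # varied exposure duration (ms), if applicable
    windows: dict  # name -> (t_start, t_end) absolute ms


@dataclass
class Protocol:
    """A named pH protocol: one continuous waveform plus sweep annotations."""

    name: str
    wave: PHWaveform
    sweeps: list[SweepInfo]
    exchange: float
    options: dict = field(default_factory=dict)


class _Builder:
    """Accumulates contiguous constant segments joined by linear exchanges."""

    def __init__(self, ph0: float, exchange: float):
        self.exchange = exchange
        self.ph = ph0
        self.wave: PHWaveform | None = None
        self.t = 0.0

    def hold(self, ph: float, duration: float) -> tuple[float, float]:
        """Switch to ``ph`` (finite exchange) and hold; returns the window
        (start of plateau after exchange, end of hold)."""
        if ph == self.ph:
            seg = make_constant(ph, duration)
            start = self.t
        else:
            seg = make_step(self.ph, ph, 0.0, self.exchange,
                            duration=self.exchange + duration)
            start = self.t  # switch begins immediately
        self.wave = seg if self.wave is None else self.wave.then(seg)
        self.ph = ph
        self.t = self.wave.duration
        return (start, self.t)


def _activation_like(test_phs, exchange, test_duration, period) -> tuple:
    b = _Builder(PH_BASE, exchange)
    sweeps = []
    for ph in test_phs:
        b.hold(PH_BASE, period - test_duration - 2 * exchange)
        w = b.hold(ph, test_duration)
        sweeps.append(SweepInfo(value=ph, duration=None,
                                windows={"test": w}))
    b.hold(PH_BASE, 2000.0)
    return b.wave, sweeps


def activation_series(test_phs=(6.8, 6.6, 6.4, 6.2, 6.0),
                      exchange: float = 1.0) -> Protocol:
    """3-s acidic stimuli every 40 s: opening and current-decay kinetics."""
    wave, sweeps = _activation_like(test_phs, exchange, 3_000.0, 40_000.0)
    return Protocol("activation_series", wave, sweeps, exchange,
                    {"test_phs": list(test_phs), "exchange": exchange})


def steady_state_activation(test_phs=(7.2, 7.1, 7.0, 6.9, 6.8, 6.7, 6.6,
                                      6.5, 6.4, 6.2, 6.0),
                            exchange: float = 200.0) -> Protocol:
    """5-s test stimuli every 50 s: the pH-activation curve."""
    wave, sweeps = _activation_like(test_phs, exchange, 5_000.0, 50_000.0)
    return Protocol("steady_state_activation", wave, sweeps, exchange,
                    {"test_phs": list(test_phs), "exchange": exchange})


def deactivation(return_phs=(7.0, 7.2, 7.4, 7.6, 7.8), stim_ph: float = PH_TEST,
                 exchange: float = 1.0) -> Protocol:
    """120-ms pH 6.0 stimulus, then return to a recovery pH: closing kinetics."""
    b = _Builder(PH_BASE, exchange)
    sweeps = []
    for ph in return_phs:
        b.hold(PH_BASE, 35_000.0)
        stim = b.hold(stim_ph, 120.0)
        tail = b.hold(ph, 3_000.0)
        sweeps.append(SweepInfo(value=ph, duration=None,
                                windows={"stim": stim, "tail": tail}))
    b.hold(PH_BASE, 2000.0)
    return Protocol("deactivation", b.wave, sweeps, exchange,
                    {"return_phs": list(return_phs), "stim_ph": stim_ph,
                     "exchange": exchange})


def ssd_curve(conditioning_phs=(7.35, 7.3, 7.25, 7.2, 7.15, 7.1, 7.05,
                                7.0, 6.9),
              exchange: float = 200.0) -> Protocol:
    """Steady-state desensitization curve: I2/I1 after 60 s of conditioning."""
    b = _Builder(PH_BASE, exchange)
    sweeps = []
    for ph in conditioning_phs:
        i1 = b.hold(PH_TEST, 8_000.0)
        b.hold(PH_BASE, 40_000.0)
        cond = b.hold(ph, 60_000.0)
        i2 = b.hold(PH_TEST, 8_000.0)
        b.hold(PH_BASE, 42_000.0)
        sweeps.append(SweepInfo(value=ph, duration=60_000.0,
                                windows={"control": i1, "conditioning": cond,
                                         "test": i2}))
    return Protocol("ssd_curve", b.wave, sweeps, exchange,
                    {"conditioning_phs": list(conditioning_phs),
                     "exchange": exchange})


def ssd_kinetics(conditioning_phs=(6.7, 6.8, 6.9, 7.0, 7.1),
                 durations_s=(0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0),
                 exchange: float = 200.0) -> Protocol:
    """Entry into SSD: test response after conditioning of growing duration."""
    b = _Builder(PH_BASE, exchange)
    sweeps = []
    for ph in conditioning_phs:
        for d in durations_s:
            ctl = b.hold(PH_TEST, 5_000.0)
            b.hold(PH_BASE, 40_000.0)
            b.hold(ph, d * 1000.0)
            tst = b.hold(PH_TEST, 5_000.0)
            b.hold(PH_BASE, 40_000.0)
            sweeps.append(SweepInfo(value=ph, duration=d * 1000.0,
                                    windows={"control": ctl, "test": tst}))
    return Protocol("ssd_kinetics", b.wave, sweeps, exchange,
                    {"conditioning_phs": list(conditioning_phs),
                     "durations_s": list(durations_s), "exchange": exchange})


def recovery_kinetics(recovery_phs=(7.3, 7.4, 7.5, 7.6, 7.8),
                      durations_s=(0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
                      exchange: float = 200.0) -> Protocol:
    """Recovery from desensitization at a recovery pH of growing duration."""
    b = _Builder(PH_BASE, exchange)
    sweeps = []
    for ph in recovery_phs:
        for d in durations_s:
            ctl = b.hold(PH_TEST, 10_000.0)
            b.hold(ph, d * 1000.0)
            tst = b.hold(PH_TEST, 5_000.0)
            b.hold(PH_BASE, 40_000.0)
            sweeps.append(SweepInfo(value=ph, duration=d * 1000.0,
                                    windows={"control": ctl, "test": tst}))
    return Protocol("recovery_kinetics", b.wave, sweeps, exchange,
                    {"recovery_phs": list(recovery_phs),
                     "durations_s": list(durations_s), "exchange": exchange})


_BUILDERS = {
    "activation_series": activation_series,
    "steady_state_activation": steady_state_activation,
    "deactivation": deactivation,
    "ssd_curve": ssd_curve,
    "ssd_kinetics": ssd_kinetics,
    "recovery_kinetics": recovery_kinetics,
}

PROTOCOL_NAMES = tuple(_BUILDERS)


def protocol_library(name: str, **options) -> Protocol:
    """Build a named protocol; unknown names raise ``KeyError``."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol {name!r}; available: {sorted(_BUILDERS)}"
        ) from None
    return builder(**options)
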