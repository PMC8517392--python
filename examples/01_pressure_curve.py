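"""Build a non-invasive LV pressure curve from cuff pressure and valve timings.

The curve is a fixed raised-cosine reference shape whose three cardiac
phases (isovolumic contraction, ejection, isovolumic relaxation) are
stretched onto the subject's own valve-event times, then scaled so the
peak equals the cuff systolic pressure.
"""

from pslwork import (
    CuffPressure,
    RAISED_COSINE_TEMPLATE,
    ValveEvents,
    pressure_at,
    scale_to_cycle,
)

# valve events from Doppler timing: MVC at 0, AVO 65 ms, AVC 370 ms, MVO 445 ms
events = ValveEvents(t_mvc=0.0, t_avo=0.065, t_avc=0.370, t_mvo=0.445)
cuff = CuffPressure(sbp=118.84, dbp=77.70)

curve = scale_to_cycle(RAISED_COSINE_TEMPLATE, events, cuff)

print(f"grid points:              {len(curve.times)}")
print(f"peak pressure (mmHg):     {curve.pressures.max():.2f}")
print(f"P at aortic opening:      {pressure_at(curve, events.t_avo):.2f}")
print(f"P at aortic closure:      {pressure_at(curve, events.t_avc):.2f}")
print(f"P at mitral opening:      {pressure_at(curve, events.t_mvo):.2f}")

# The peak equals the cuff SBP by construction (peak LV pressure is assumed
# equal to peak arterial pressure); the anchor values at the valve events are
# the template's boundary levels (90%, 55%, 10% of SBP).
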