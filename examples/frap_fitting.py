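"""FRAP analysis: masking, corrections, binning, and exponential fits.

Simulates a confocal FRAP movie of a nucleus with double-exponential
ground-truth recovery (A1=0.5, tau1=2 s; A2=0.3, tau2=30 s; 20% of the
bleached signal never recovers), then runs the full pipeline: nuclear
masking, background subtraction, two-anchor photobleach correction,
curve extraction, log-spaced binning, the gradient-smoothing test for
diffusion coupling, and constrained exponential fits.
"""
import smtkit as sk
from smtkit.frap import gradient_smoothing_test, nuclear_mask, \
    background_subtract, photobleach_correct

cfg = sk.FrapSimConfig(a1=0.5, tau1_s=2.0, a2=0.3, tau2_s=30.0,
                       noise_sd=0.02, obs_bleach_rate=0.002, seed=1)
stack, timestamps, geom = sk.simulate_frap_movie(cfg)

curve = sk.analyze_frap_movie(stack, timestamps, geom["spot_center_px"],
                              geom["spot_radius_px"], geom["bleach_frame"])
print(f"binned recovery curve: {len(curve.times)} points, "
      f"t = {curve.times.min():.2f}-{curve.times.max():.1f} s")

# is recovery reaction-limited? (radial bleach profile keeps its shape)
mask = nuclear_mask(stack)
corrected = photobleach_correct(background_subtract(stack, mask), mask,
                                geom["bleach_frame"])
_, diffusive = gradient_smoothing_test(corrected, timestamps,
                                       geom["spot_center_px"],
                                       geom["bleach_frame"])
print(f"gradient-smoothing test flags diffusion: {diffusive}")
t70 = sk.diffusion_timescale(geom['spot_radius_um'], 2.0)
print(f"(free molecules at D=2 µm²/s cross the {geom['spot_radius_um']} µm "
      f"spot in ~{t70*1000:.0f} ms, far below the frame interval, so "
      f"diffusion is invisible and a reaction model applies)")

single = sk.fit_single_exp(curve)
double = sk.fit_double_exp(curve)
p = double.params
print(f"single-exponential: A={single.params['A']:.2f} "
      f"tau={single.params['tau']:.1f} s (rss {single.rss:.4f})")
print(f"double-exponential: A1={p['A1']:.2f} tau1={p['tau1']:.1f} s, "
      f"A2={p['A2']:.2f} tau2={p['tau2']:.1f} s (rss {double.rss:.4f})")
print("the double fit's lower residual and two separated timescales "
      "indicate two bound populations with distinct residence times")
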