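"""Count complete channel crossings and compute the ionic current.

Synthetic ion tracks realise a known schedule of complete crossings
plus incomplete entries (feints); the three-state counter recovers the
schedule exactly and I = N q / tau converts net counts to current.
"""

from rigidbd import compute_current, count_crossings, make_ion_tracks

schedule = [("Na+", 3, 1, 2), ("Cl-", 5, 0, 1), ("Na+", 0, 0, 4)]
tracks = make_ion_tracks(schedule, slab=(-20.0, 20.0), noise=0.5, seed=1)

counts = {}
for (track, truth) in tracks:
    up, down = count_crossings(track)
    print(f"ion {track.ion_id} ({track.species}): counted up={up} down={down}, "
          f"scheduled {truth}")
    c = counts.setdefault(track.species, [0, 0])
    c[0] += up
    c[1] += down

tau = 80e-9  # an 80 ns observation window
result = compute_current({k: tuple(v) for k, v in counts.items()}, tau)
for sp, current in result.current_A.items():
    print(f"{sp}: net {result.net[sp]:+d} crossings -> {current * 1e12:+.1f} pA")
print(f"total current {result.total_pA:+.1f} pA over tau = {tau * 1e9:.0f} ns")
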