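"""Build one synthetic two-view posture, measure its ten components and score it.

The skeleton is constructed with known joint deviations (degrees), so the
printed "measured" column demonstrates that the vector-geometry layer
recovers exactly what was posed; the category/points columns show how the
assessment bands translate angles into the 10-26 point scorecard.
"""

from mdopac import SkeletonSpec, generate_capture, measure_component, rate_component
from mdopac.geometry import ComponentID
from mdopac.scoring import build_scorecard

angles = {
    ComponentID.HIP_LEVEL: 2.0,        # hips near level
    ComponentID.TRUNK_FB: 28.0,        # leaning over the patient
    ComponentID.TRUNK_SS: 5.0,
    ComponentID.NECK_FRONT: 47.0,      # heavy neck flexion -> harmful
    ComponentID.NECK_SIDE: 12.0,
    ComponentID.SHOULDER_RELAXED: 8.0,
    ComponentID.SHOULDER_LEVEL: 3.0,
    ComponentID.UPPER_ARM: 14.0,       # moderate abduction -> compromised
    ComponentID.ELBOW: 10.0,           # forearm near waist level
    ComponentID.WRIST: 18.0,           # flexed past the 15 deg tolerance
}

capture = generate_capture(SkeletonSpec(subject_id="demo", angles=angles))
ratings = []
print(f"{'component':18s} {'posed':>7s} {'measured':>9s}  category      points")
for comp in ComponentID:
    m = measure_component(capture, comp)
    r = rate_component(m)
    ratings.append(r)
    print(
        f"{comp.value:18s} {angles[comp]:7.2f} {m.value:9.4f}  "
        f"{r.category:12s}  {r.points}"
    )

card = build_scorecard(ratings, "demo")
print(f"\ntotal score: {card.total} (range 10-26) -> overall {card.overall}")
print("A total of 10 would be ideal; 11-20 is compromised; >=21 harmful.")
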