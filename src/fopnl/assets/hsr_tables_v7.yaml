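# Health Star Rating point tables and star-conversion matrices (table-driven,
# transcription of the published industry calculator guide, v7 era).
#
# Band convention used throughout: each `edges` list holds the LOWER edges of
# successive bands, closed on the lower edge and open above, so a value v
# scores points[k] where k = number of edges <= v. `points` therefore has one
# more entry than `edges` and must be non-decreasing.
#
# Star matrices list ascending score upper bounds with descending star values;
# `max: null` is the catch-all for the highest (worst) scores.
version: "hsr-v7-2023"

baseline:
  # kJ per 100 g/mL, 1 point per 335 kJ band up to 10 points
  energy:
    edges: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
    points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
  # g per 100 g/mL; 1 g bands to 10 points, then geometric extension to 30
  saturated_fat:
    edges: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
            11.2, 12.5, 13.9, 15.5, 17.3, 19.3, 21.6, 24.1, 26.9, 30.0,
            33.5, 37.4, 41.7, 46.6, 52.0, 58.0, 64.7, 72.3, 80.7, 90.0]
    points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
             11, 12, 13, 14, 15, 16, 17, 18, 19, 20,
             21, 22, 23, 24, 25, 26, 27, 28, 29, 30]
  # g per 100 g/mL
  total_sugar:
    edges: [5.0, 8.9, 12.8, 16.8, 20.7, 24.6, 28.5, 32.4, 36.3, 40.2,
            44.5, 48.3, 52.1, 55.9, 59.7, 63.5, 67.3, 71.1, 74.9, 78.7, 82.5, 86.3]
    points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
             11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22]
  # mg per 100 g/mL; 90 mg bands to 10 points, then geometric extension to 30
  sodium:
    edges: [90, 180, 270, 360, 450, 540, 630, 720, 810, 900,
            1005, 1121, 1251, 1397, 1559, 1740, 1942, 2167, 2418, 2699,
            3012, 3361, 3751, 4186, 4672, 5214, 5819, 6494, 7247, 8088]
    points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
             11, 12, 13, 14, 15, 16, 17, 18, 19, 20,
             21, 22, 23, 24, 25, 26, 27, 28, 29, 30]

modifying:
  # combined FVNL percentage (concentrated content already folded in via the
  # combination formula below); the 100% band needs >= 99.9 to absorb
  # floating-point residue of the combination formula
  fvnl:
    edges: [40, 60, 80, 99.9]
    points: [0, 1, 2, 5, 8]
  # g protein per 100 g/mL; 1.6 g bands to 10 points, extension to 15
  protein:
    edges: [1.6, 3.2, 4.8, 6.4, 8.0, 9.6, 11.2, 12.8, 14.4, 16.0,
            17.8, 19.8, 22.0, 24.4, 27.1]
    points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]
  # g dietary fiber per 100 g/mL
  fiber:
    edges: [0.9, 1.9, 2.8, 3.7, 4.7, 5.4, 6.3, 7.3, 8.4, 9.7,
            11.2, 13.0, 15.0, 17.3, 20.0]
    points: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15]

# combined FVNL% = (nonconc + w*conc) / (100 + (w-1)*conc) * 100, w = weight
fvnl_combination:
  concentrated_weight: 2.0

# P points are only awarded when baseline < threshold OR V points >= min_v
protein_cap:
  baseline_threshold: 13
  min_v_points: 5

# which modifying components apply per HSR category
applicability:
  C1:  {v: true, p: false, f: false}
  C1D: {v: true, p: true,  f: true}
  C2:  {v: true, p: true,  f: true}
  C2D: {v: true, p: true,  f: true}

star_matrix:
  C1:
    - {max: -6, stars: 5.0}
    - {max: -5, stars: 4.5}
    - {max: -4, stars: 4.0}
    - {max: -3, stars: 3.5}
    - {max: -2, stars: 3.0}
    - {max: -1, stars: 2.5}
    - {max: 0, stars: 2.0}
    - {max: 1, stars: 1.5}
    - {max: 2, stars: 1.0}
    - {max: null, stars: 0.5}
  C1D:
    - {max: -3, stars: 5.0}
    - {max: -2, stars: 4.5}
    - {max: -1, stars: 4.0}
    - {max: 0, stars: 3.5}
    - {max: 1, stars: 3.0}
    - {max: 2, stars: 2.5}
    - {max: 3, stars: 2.0}
    - {max: 5, stars: 1.5}
    - {max: 7, stars: 1.0}
    - {max: null, stars: 0.5}
  C2:
    - {max: -11, stars: 5.0}
    - {max: -7, stars: 4.5}
    - {max: -2, stars: 4.0}
    - {max: 2, stars: 3.5}
    - {max: 6, stars: 3.0}
    - {max: 10, stars: 2.5}
    - {max: 14, stars: 2.0}
    - {max: 18, stars: 1.5}
    - {max: 22, stars: 1.0}
    - {max: null, stars: 0.5}
  C2D:
    - {max: -6, stars: 5.0}
    - {max: -4, stars: 4.5}
    - {max: -1, stars: 4.0}
    - {max: 1, stars: 3.5}
    - {max: 3, stars: 3.0}
    - {max: 6, stars: 2.5}
    - {max: 9, stars: 2.0}
    - {max: 12, stars: 1.5}
    - {max: 15, stars: 1.0}
    - {max: null, stars: 0.5}

# five-grade summary mapping (half-open star bands, descending)
grade_map:
  A: 4.5
  B: 3.0
  C: 2.0
  D: 1.0
  E: 0.5

# ingredient markers used as a fallback for dairy/non-dairy routing when the
# subgroup carries no HSR category hint
dairy_markers: [milk, yogurt, yoghurt, whey, cream, butter, cheese, curd]
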