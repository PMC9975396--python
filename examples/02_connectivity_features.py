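"""From raw network time series to the 91-feature connectivity vector.

Also demonstrates the head-motion rejection rule: a scan is excluded when
framewise displacement or any translation exceeds 3 mm, or any rotation
exceeds 3 degrees.
"""

from fcnorm import correlation_matrix, motion_qc, vectorize
from fcnorm.simulate import (
    generate_motion_table,
    make_base_correlation,
    sample_subject_timeseries,
)

# motion QC on a clean and a contaminated scan
clean = generate_motion_table(150, contaminate=False, seed=0)
bad = generate_motion_table(150, contaminate=True, seed=0)
print("clean scan:", motion_qc(clean))
print("contaminated scan:", motion_qc(bad))

# one subject's connectivity features
template = make_base_correlation(seed=0)
ts = sample_subject_timeseries(template, subject_sd=0.06, n_timepoints=150, seed=1)
conn = correlation_matrix(ts)
vec = vectorize(conn, subject_id="demo")

print(f"\nconnectivity matrix shape: {conn.values.shape}")
print(f"feature vector length: {vec.values.shape[0]}")
print(f"first three features {vec.values[:3].round(3)} correspond to pairs "
      f"{[vec.pair_index[k] for k in range(3)]}")
print("each feature is the Pearson correlation between one unordered pair "
      "of networks; 14 networks give 14*13/2 = 91 pairs.")
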