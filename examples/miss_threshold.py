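"""How many consecutive misses should a tracker tolerate?

With independent per-frame detections at probability p_d, a target is seen
at least once in d-bar consecutive frames with probability
1 - (1 - p_d)^d-bar.  The smallest d-bar reaching a target confidence pi
is the natural termination threshold for the miss counter.
"""

from spermtrack import required_miss_threshold

print("p_d    pi     required d-bar")
for p_d, pi in [(0.67, 0.99), (0.5, 0.9), (0.8, 0.99), (0.9, 0.999)]:
    d_bar = required_miss_threshold(p_d, pi)
    reached = 1 - (1 - p_d) ** d_bar
    print(f"{p_d:.2f}   {pi:.3f}  {d_bar}   (prob of >=1 look: {reached:.4f})")
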