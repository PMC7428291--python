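# Approximate default layout for shape L (flat, 10 cubes).
# One cube per line: ix iy iz material. Replace with your own if known.
0 0 0 wood
1 0 0 wood
2 0 0 wood
3 0 0 wood
4 0 0 wood
5 0 0 wood
0 1 0 wood
0 2 0 wood
0 3 0 wood
0 4 0 wood
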