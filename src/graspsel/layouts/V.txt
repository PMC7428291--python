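# Approximate default layout for shape V (flat, two arms, 10 cubes).
0 0 0 wood
1 0 0 wood
2 0 0 wood
3 0 0 wood
4 0 0 wood
0 1 0 wood
0 2 0 wood
1 2 0 wood
1 3 0 wood
1 4 0 wood
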