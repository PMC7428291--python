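# Approximate default layout for shape U (stacked, 10 cubes).
0 0 0 wood
1 0 0 wood
2 0 0 wood
3 0 0 wood
0 0 1 wood
3 0 1 wood
0 0 2 wood
3 0 2 wood
0 0 3 wood
3 0 3 wood
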