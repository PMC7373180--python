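<?xml version='1.0' encoding='UTF-8'?>
<svg xmlns="http://www.w3.org/2000/svg" version="1.1" viewBox="7.806 8.53 504.208 334.141" width="504.208" height="334.141">
  <g id="g_c0">
    <path d="M 32.806 18.53 L 487.015 18.53 C 495.299 18.53 502.015 25.246 502.015 33.53 L 502.015 317.672 C 502.015 325.956 495.299 332.672 487.015 332.672 L 32.806 332.672 C 24.522 332.672 17.806 325.956 17.806 317.672 L 17.806 33.53 C 17.806 25.246 24.522 18.53 32.806 18.53 Z" fill="#FFFFFF" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_c1">
    <path d="M 44.806 30.53 L 475.015 30.53 C 483.299 30.53 490.015 37.246 490.015 45.53 L 490.015 305.672 C 490.015 313.956 483.299 320.672 475.015 320.672 L 44.806 320.672 C 36.522 320.672 29.806 313.956 29.806 305.672 L 29.806 45.53 C 29.806 37.246 36.522 30.53 44.806 30.53 Z" fill="#FFFFFF" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_s0">
    <path d="M 69.806 62.085 L 175.806 62.085 L 187.806 74.085 L 187.806 134.085 L 175.806 146.085 L 69.806 146.085 L 57.806 134.085 L 57.806 74.085 L 69.806 62.085 Z" fill="#E6E6FA" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_s1">
    <path d="M 74.056 74.085 L 161.556 74.085 C 165.008 74.085 167.806 76.883 167.806 80.335 L 167.806 92.835 C 167.806 96.286 165.008 99.085 161.556 99.085 L 74.056 99.085 C 70.604 99.085 67.806 96.286 67.806 92.835 L 67.806 80.335 C 67.806 76.883 70.604 74.085 74.056 74.085 Z" fill="#CCFFCC" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_s2">
    <path d="M 74.056 105.085 L 161.556 105.085 C 165.008 105.085 167.806 107.883 167.806 111.335 L 167.806 123.835 C 167.806 127.286 165.008 130.085 161.556 130.085 L 74.056 130.085 C 70.604 130.085 67.806 127.286 67.806 123.835 L 67.806 111.335 C 67.806 107.883 70.604 105.085 74.056 105.085 Z" fill="#CCFFCC" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_s3">
    <path d="M 211.583 58.53 L 311.583 58.53 L 311.583 98.53 C 311.583 104.053 307.106 108.53 301.583 108.53 L 221.583 108.53 C 216.06 108.53 211.583 104.053 211.583 98.53 L 211.583 58.53 Z" fill="#FFFFB3" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_s4">
    <path d="M 374.973 59.697 L 444.973 59.697 L 459.973 84.697 L 444.973 109.697 L 374.973 109.697 L 359.973 84.697 L 374.973 59.697 Z" fill="#FFFFFF" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_s5">
    <ellipse cx="110.91" cy="176.732" rx="50" ry="25" fill="#FFCC99" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_s6">
    <path d="M 217.563 147.17 L 297.563 147.17 C 303.086 147.17 307.563 151.647 307.563 157.17 L 307.563 187.17 C 307.563 192.693 303.086 197.17 297.563 197.17 L 217.563 197.17 C 212.04 197.17 207.563 192.693 207.563 187.17 L 207.563 157.17 C 207.563 151.647 212.04 147.17 217.563 147.17 Z" fill="#CCFFCC" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_s7">
    <path d="M 372.015 149.597 L 452.015 149.597 C 457.538 149.597 462.015 154.074 462.015 159.597 L 462.015 189.597 C 462.015 195.12 457.538 199.597 452.015 199.597 L 372.015 199.597 C 366.492 199.597 362.015 195.12 362.015 189.597 L 362.015 159.597 C 362.015 154.074 366.492 149.597 372.015 149.597 Z" fill="#CCFFCC" stroke="#000000" stroke-width="1"/>
    <ellipse cx="374.015" cy="149.597" rx="7" ry="7" fill="#FFFFFF" stroke="#000000" stroke-width="1"/>
    <text x="374.015" y="149.597" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="8" fill="#000000">P</text>
  </g>
  <g id="g_s8">
    <ellipse cx="111.574" cy="262.013" rx="50" ry="25" fill="#FFCC99" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_s9">
    <path d="M 209.672 241.329 L 309.672 241.329 L 309.672 281.329 C 309.672 286.852 305.195 291.329 299.672 291.329 L 219.672 291.329 C 214.149 291.329 209.672 286.852 209.672 281.329 L 209.672 241.329 Z" fill="#FFFFB3" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_s9_dup">
    <path d="M 358.373 242.672 L 458.373 242.672 L 458.373 282.672 C 458.373 288.195 453.896 292.672 448.373 292.672 L 368.373 292.672 C 362.85 292.672 358.373 288.195 358.373 282.672 L 358.373 242.672 Z" fill="#FFFFB3" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_r0">
    <path d="M 122.806 104.085 L 261.583 83.53" fill="none" stroke="#000000" stroke-width="1"/>
    <path d="M 188.194 89.808 L 196.194 89.808 L 196.194 97.808 L 188.194 97.808 L 188.194 89.808 Z" fill="#FFFFFF" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_r1">
    <path d="M 261.583 83.53 L 409.973 84.697" fill="none" stroke="#000000" stroke-width="1"/>
    <path d="M 331.778 80.114 L 339.778 80.114 L 339.778 88.114 L 331.778 88.114 L 331.778 80.114 Z" fill="#FFFFFF" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_r2">
    <path d="M 409.973 84.697 L 110.91 176.732" fill="none" stroke="#000000" stroke-width="1"/>
    <path d="M 256.441 126.715 L 264.441 126.715 L 264.441 134.715 L 256.441 134.715 L 256.441 126.715 Z" fill="#FFFFFF" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_r3">
    <path d="M 110.91 176.732 L 257.563 172.17" fill="none" stroke="#000000" stroke-width="1"/>
    <path d="M 180.236 170.451 L 188.236 170.451 L 188.236 178.451 L 180.236 178.451 L 180.236 170.451 Z" fill="#FFFFFF" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_r4">
    <path d="M 257.563 172.17 L 412.015 174.597" fill="none" stroke="#000000" stroke-width="1"/>
    <path d="M 330.789 169.383 L 338.789 169.383 L 338.789 177.383 L 330.789 177.383 L 330.789 169.383 Z" fill="#FFFFFF" stroke="#000000" stroke-width="1"/>
  </g>
  <g id="g_s0_label">
    <text x="122.806" y="137.085" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">SP0</text>
  </g>
  <g id="g_s1_label">
    <text x="117.806" y="86.585" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">SP1</text>
  </g>
  <g id="g_s2_label">
    <text x="117.806" y="117.585" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">SP2</text>
  </g>
  <g id="g_s3_label">
    <text x="261.583" y="83.53" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">SP3</text>
  </g>
  <g id="g_s4_label">
    <text x="409.973" y="84.697" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">SP4</text>
  </g>
  <g id="g_s5_label">
    <text x="110.91" y="176.732" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">SP5</text>
  </g>
  <g id="g_s6_label">
    <text x="257.563" y="172.17" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">SP6</text>
  </g>
  <g id="g_s7_label">
    <text x="412.015" y="174.597" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">SP7</text>
  </g>
  <g id="g_s8_label">
    <text x="111.574" y="262.013" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">SP8</text>
  </g>
  <g id="g_s9_label">
    <text x="259.672" y="266.329" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">SP9</text>
  </g>
  <g id="g_s9_dup_label">
    <text x="408.373" y="267.672" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">SP9</text>
  </g>
  <g id="g_c0_label">
    <text x="259.91" y="27.53" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">compartment_0</text>
  </g>
  <g id="g_c1_label">
    <text x="259.91" y="39.53" text-anchor="middle" dominant-baseline="central" font-family="sans-serif" font-size="11" fill="#000000">compartment_1</text>
  </g>
</svg>
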