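<fluxml name="branch_cycle">
  <reactionnetwork>
    <metabolitepools>
      <pool id="SA" atoms="3" type="input"/>
      <pool id="SB" atoms="2" type="input"/>
      <pool id="A" atoms="3" type="intra"/>
      <pool id="B" atoms="2" type="intra"/>
      <pool id="C" atoms="1" type="intra"/>
      <pool id="E" atoms="3" type="intra"/>
      <pool id="P" atoms="3" type="output"/>
      <pool id="R" atoms="2" type="output"/>
      <pool id="Q" atoms="1" type="output"/>
    </metabolitepools>
    <reaction id="upt_a">
      <reduct id="SA" cx="abc"/>
      <rproduct id="A" cx="abc"/>
    </reaction>
    <reaction id="upt_b">
      <reduct id="SB" cx="ab"/>
      <rproduct id="B" cx="ab"/>
    </reaction>
    <reaction id="split">
      <reduct id="A" cx="abc"/>
      <rproduct id="B" cx="ab"/>
      <rproduct id="C" cx="c"/>
    </reaction>
    <reaction id="alt">
      <reduct id="A" cx="abc"/>
      <rproduct id="E" cx="acb"/>
    </reaction>
    <reaction id="cond" bidirectional="true">
      <reduct id="B" cx="ab"/>
      <reduct id="C" cx="c"/>
      <rproduct id="E" cx="abc"/>
    </reaction>
    <reaction id="out_e">
      <reduct id="E" cx="abc"/>
      <rproduct id="P" cx="abc"/>
    </reaction>
    <reaction id="out_b">
      <reduct id="B" cx="ab"/>
      <rproduct id="R" cx="ab"/>
    </reaction>
    <reaction id="out_c">
      <reduct id="C" cx="a"/>
      <rproduct id="Q" cx="a"/>
    </reaction>
  </reactionnetwork>
  <constraints>
    <net>
      <bounds lo="-100.0" hi="100.0"/>
      <textual>split &gt;= 5.0; alt &gt;= 5.0; out_c &gt;= 1.0; out_b &gt;= 1.0; upt_b &gt;= 1.0</textual>
    </net>
    <xch>
      <bounds lo="0.0" hi="200.0"/>
    </xch>
  </constraints>
  <measurement>
    <mgroup id="ms_P" spec="P[1,2,3]#M0,1,2,3"/>
    <mgroup id="ms_P12" spec="P[1,2]#M0,1,2"/>
    <mgroup id="ms_R" spec="R[1,2]#M0,1,2"/>
    <mgroup id="ms_Q" spec="Q[1]#M0,1"/>
    <errormodel slope="0.0412" intercept="0.006655"/>
    <rate flux="upt_b" value="20.0" stddev="1.0"/>
    <rate flux="out_e" value="90.0" stddev="4.5"/>
  </measurement>
  <normalization flux="upt_a" value="100.0" fixed="true"/>
</fluxml>
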